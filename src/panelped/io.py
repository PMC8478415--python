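"""Readers and writers for pedigree tables and parameter databases.

Pedigrees are CSV/TSV files with a header row in the standard column
schema: ``ID``, ``MotherID``, ``FatherID``, ``Sex``, ``isProband``,
``CurAge``, ``isDead``, ``race``, ``Ancestry``, ``Twins``, ``riskmod``,
``InterAge``, matched ``isAff*``/``Age*`` pairs per cancer tag, plus
optional germline-result columns named after genes and marker-result
columns (ER, PR, HER2, CK14, CK5.6, MSI).  ``NA`` or an empty cell means
missing.  List-valued cells (riskmod/InterAge) are semicolon-separated.

Parameter databases live either in an HDF5 container (datasets =
arrays, attributes = axis labels) or in an equivalent JSON dialect used
for small toy databases; :func:`load_database` dispatches on the file
suffix.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Union

import h5py
import numpy as np
import pandas as pd

from .core import (
    ANCESTRIES, GENE_TYPES, MARKER_TYPES, PENETRANCE_TYPES, SEXES,
    AlleleFrequencyTable, CancerHistory, DatabaseError, Individual,
    ParameterDatabase, Pedigree, PenetranceTable, SchemaError,
)

MANDATORY_COLUMNS = ("ID", "MotherID", "FatherID", "Sex")
LIST_SEP = ";"


def _opt_int(value) -> Optional[int]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, str):
        value = value.strip()
        if value in ("", "NA", "NaN", "nan"):
            return None
    return int(float(value))


def _opt_str(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    return None if s in ("", "NA") else s


def _split_list(value) -> List[str]:
    s = _opt_str(value)
    if s is None:
        return []
    return [tok.strip() for tok in s.split(LIST_SEP) if tok.strip()]


def read_pedigree(path: Union[str, Path]) -> Pedigree:
    """Read a pedigree from a CSV or TSV file.

    Raises :class:`SchemaError` if a mandatory column is absent or an
    ``isAff*`` column has no matching ``Age*`` column (or vice versa).
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                     keep_default_na=False, na_values=["NA", ""])
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"pedigree file is missing mandatory column '{col}'")

    aff_tags = [c[len("isAff"):] for c in df.columns if c.startswith("isAff")]
    age_tags = [c[len("Age"):] for c in df.columns if c.startswith("Age") and c != "Age"]
    for tag in aff_tags:
        if tag not in age_tags:
            raise SchemaError(f"column isAff{tag} has no matching Age{tag} column")
    for tag in age_tags:
        if tag not in aff_tags:
            raise SchemaError(f"column Age{tag} has no matching isAff{tag} column")

    gene_cols = [c for c in df.columns if c in GENE_TYPES]
    marker_cols = [c for c in df.columns if c in MARKER_TYPES]

    members = []
    for _, row in df.iterrows():
        iid = _opt_int(row["ID"])
        if iid is None:
            raise SchemaError("pedigree contains a row with missing ID")
        cancers = {}
        for tag in aff_tags:
            aff = _opt_int(row[f"isAff{tag}"])
            cancers[tag] = CancerHistory(affected=0 if aff is None else aff,
                                         diagnosis_age=_opt_int(row[f"Age{tag}"]))
        kinds = _split_list(row.get("riskmod"))
        ages = [int(a) for a in _split_list(row.get("InterAge"))]
        if len(kinds) != len(ages):
            raise SchemaError(f"ID {iid}: riskmod and InterAge lists differ in length")
        germline = {}
        for g in gene_cols:
            v = _opt_int(row[g])
            if v is not None:
                germline[g] = v
        markers = {}
        for m in marker_cols:
            v = _opt_int(row[m])
            if v is not None:
                markers[m] = v
        members.append(Individual(
            id=iid,
            mother_id=_opt_int(row["MotherID"]),
            father_id=_opt_int(row["FatherID"]),
            sex=int(_opt_int(row["Sex"]) or 0) if _opt_int(row["Sex"]) is not None else 0,
            is_proband=_opt_int(row.get("isProband")) or 0,
            cur_age=_opt_int(row.get("CurAge")),
            is_dead=_opt_int(row.get("isDead")),
            cancers=cancers,
            race=_opt_str(row.get("race")),
            ancestry=_opt_str(row.get("Ancestry")),
            twin_group=_opt_int(row.get("Twins")) or 0,
            interventions=list(zip(kinds, ages)),
            germline=germline,
            markers=markers,
            pseudo=bool(_opt_int(row.get("pseudo")) or 0),
        ))
    return Pedigree.from_members(members, cancers=aff_tags)


def write_pedigree(ped: Pedigree, path: Union[str, Path]) -> None:
    """Write a pedigree as CSV; round-trips through :func:`read_pedigree`."""
    rows = []
    gene_cols = sorted({g for m in ped for g in m.germline})
    marker_cols = sorted({g for m in ped for g in m.markers})
    any_pseudo = any(m.pseudo for m in ped)
    for m in ped:
        row: Dict[str, object] = {
            "ID": m.id,
            "MotherID": m.mother_id if m.mother_id is not None else "NA",
            "FatherID": m.father_id if m.father_id is not None else "NA",
            "Sex": m.sex,
            "isProband": m.is_proband,
            "CurAge": m.cur_age if m.cur_age is not None else "NA",
            "isDead": m.is_dead if m.is_dead is not None else "NA",
            "race": m.race if m.race is not None else "NA",
            "Ancestry": m.ancestry if m.ancestry is not None else "NA",
            "Twins": m.twin_group,
            "riskmod": LIST_SEP.join(k for k, _ in m.interventions) or "NA",
            "InterAge": LIST_SEP.join(str(a) for _, a in m.interventions) or "NA",
        }
        for tag in ped.cancers:
            hist = m.cancers.get(tag, CancerHistory())
            row[f"isAff{tag}"] = hist.affected
            row[f"Age{tag}"] = hist.diagnosis_age if hist.diagnosis_age is not None else "NA"
        for g in gene_cols:
            row[g] = m.germline.get(g, "NA")
        for mk in marker_cols:
            row[mk] = m.markers.get(mk, "NA")
        if any_pseudo:
            row["pseudo"] = int(m.pseudo)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Parameter database container
# ---------------------------------------------------------------------------

def _db_to_dict(db: ParameterDatabase) -> dict:
    return {
        "Penetrance": {
            "shape": list(db.penetrance.values.shape),
            "values": np.asarray(db.penetrance.values, dtype=float).ravel().tolist(),
            "Cancer": db.penetrance.cancers,
            "Gene": db.penetrance.gene_variants,
            "Race": db.penetrance.races,
            "Sex": list(db.penetrance.sexes),
            "PenetType": list(db.penetrance.types),
        },
        "AlleleFrequency": {
            "shape": list(db.allele_frequency.values.shape),
            "values": np.asarray(db.allele_frequency.values, dtype=float).ravel().tolist(),
            "Gene": db.allele_frequency.genes,
            "Ancestry": list(db.allele_frequency.ancestries),
        },
        "GeneVariantMap": db.gene_variant_map,
        "CancerTags": db.cancer_tags,
        "RiskModifiers": [[k[0], k[1], v] for k, v in db.risk_modifiers.items()],
        "MarkerTables": db.marker_tables,
    }


def _db_from_dict(doc: dict) -> ParameterDatabase:
    if "Penetrance" not in doc:
        raise DatabaseError("container is missing the Penetrance table")
    if "AlleleFrequency" not in doc:
        raise DatabaseError("container is missing the AlleleFrequency table")
    pen = doc["Penetrance"]
    freq = doc["AlleleFrequency"]
    pen_table = PenetranceTable(
        values=np.asarray(pen["values"], dtype=float).reshape(pen["shape"]),
        cancers=list(pen["Cancer"]),
        gene_variants=list(pen["Gene"]),
        races=list(pen["Race"]),
        sexes=tuple(pen.get("Sex", SEXES)),
        types=tuple(pen.get("PenetType", PENETRANCE_TYPES)),
    )
    freq_table = AlleleFrequencyTable(
        values=np.asarray(freq["values"], dtype=float).reshape(freq["shape"]),
        genes=list(freq["Gene"]),
        ancestries=tuple(freq.get("Ancestry", ANCESTRIES)),
    )
    risk_mod = {(kind, cancer): float(factor)
                for kind, cancer, factor in doc.get("RiskModifiers", [])}
    db = ParameterDatabase(
        penetrance=pen_table,
        allele_frequency=freq_table,
        gene_variant_map=dict(doc.get("GeneVariantMap", {})),
        cancer_tags=dict(doc.get("CancerTags", {})),
        risk_modifiers=risk_mod,
        marker_tables={k: dict(v) for k, v in doc.get("MarkerTables", {}).items()},
    )
    db.validate()
    return db


def save_database(db: ParameterDatabase, path: Union[str, Path]) -> None:
    """Write a database container (JSON for ``.json`` paths, else HDF5)."""
    path = Path(path)
    doc = _db_to_dict(db)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(doc))
        return
    with h5py.File(path, "w") as f:
        pen = f.create_group("Penetrance")
        pen.create_dataset("values", data=db.penetrance.values)
        pen.attrs["Cancer"] = db.penetrance.cancers
        pen.attrs["Gene"] = db.penetrance.gene_variants
        pen.attrs["Race"] = db.penetrance.races
        pen.attrs["Sex"] = list(db.penetrance.sexes)
        pen.attrs["PenetType"] = list(db.penetrance.types)
        freq = f.create_group("AlleleFrequency")
        freq.create_dataset("values", data=db.allele_frequency.values)
        freq.attrs["Gene"] = db.allele_frequency.genes
        freq.attrs["Ancestry"] = list(db.allele_frequency.ancestries)
        meta = f.create_group("Meta")
        meta.attrs["GeneVariantMap"] = json.dumps(db.gene_variant_map)
        meta.attrs["CancerTags"] = json.dumps(db.cancer_tags)
        meta.attrs["RiskModifiers"] = json.dumps(doc["RiskModifiers"])
        meta.attrs["MarkerTables"] = json.dumps(db.marker_tables)


def load_database(path: Union[str, Path]) -> ParameterDatabase:
    """Load and validate a parameter database container.

    Raises :class:`DatabaseError` if a table is missing, a probability
    falls outside [0, 1], or any age slice sums above 1.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        return _db_from_dict(json.loads(path.read_text()))
    with h5py.File(path, "r") as f:
        if "Penetrance" not in f:
            raise DatabaseError("container is missing the Penetrance table")
        if "AlleleFrequency" not in f:
            raise DatabaseError("container is missing the AlleleFrequency table")

        def labels(grp, key):
            return [x.decode() if isinstance(x, bytes) else str(x)
                    for x in grp.attrs[key]]

        pen = f["Penetrance"]
        freq = f["AlleleFrequency"]
        meta = f["Meta"] if "Meta" in f else None
        doc = {
            "Penetrance": {
                "shape": list(pen["values"].shape),
                "values": np.asarray(pen["values"]).ravel(),
                "Cancer": labels(pen, "Cancer"),
                "Gene": labels(pen, "Gene"),
                "Race": labels(pen, "Race"),
                "Sex": labels(pen, "Sex"),
                "PenetType": labels(pen, "PenetType"),
            },
            "AlleleFrequency": {
                "shape": list(freq["values"].shape),
                "values": np.asarray(freq["values"]).ravel(),
                "Gene": labels(freq, "Gene"),
                "Ancestry": labels(freq, "Ancestry"),
            },
        }
        if meta is not None:
            doc["GeneVariantMap"] = json.loads(meta.attrs["GeneVariantMap"])
            doc["CancerTags"] = json.loads(meta.attrs["CancerTags"])
            doc["RiskModifiers"] = json.loads(meta.attrs["RiskModifiers"])
            doc["MarkerTables"] = json.loads(meta.attrs["MarkerTables"])
    return _db_from_dict(doc)
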