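"""Readers and writers for the pipeline's plain-text dialects.

All tables are tab-separated UTF-8 with '#'-prefixed comment lines
permitted and '.' as the decimal point.  Gene and miRNA identifiers are
opaque, case-sensitive strings.  Readers raise errors naming the file,
line and violated expectation; every writer/reader pair round-trips its
canonical form exactly.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .enrichment import GeneSetCollection
from .matrix import ExpressionMatrix, PairingTable
from .qpcr import validate_ct_table
from .survival import validate_survival_table
from .synthetic import TargetResource


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", encoding="utf-8", **kwargs)
    except Exception as exc:  # re-raise with the file named
        raise ValueError(f"{path}: cannot parse TSV ({exc})") from exc


# -- expression matrices ----------------------------------------------------

def write_expression_tsv(expr: ExpressionMatrix, path, meta_path=None) -> None:
    df = expr.values.copy()
    df.index.name = "feature"
    df.to_csv(path, sep="\t", encoding="utf-8")
    if meta_path is not None:
        meta = expr.sample_meta.copy()
        meta.index.name = "sample"
        meta.to_csv(meta_path, sep="\t", encoding="utf-8")


def read_expression_tsv(path, meta_path=None, scale: str = "counts") -> ExpressionMatrix:
    # pandas silently renames duplicate header fields, so inspect the raw header
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                header = line.rstrip("\n").split("\t")[1:]
                break
        else:
            raise ValueError(f"{path}: empty file")
    dup = sorted({s for s in header if header.count(s) > 1})
    if dup:
        raise ValueError(f"{path}: duplicated sample id(s) in header: {dup}")
    df = _read_tsv(path, index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"{path}: duplicated feature id(s): {dup}")
    if meta_path is not None:
        meta = _read_tsv(meta_path, index_col=0)
        missing = [c for c in ("patient", "phase") if c not in meta.columns]
        if missing:
            raise ValueError(f"{meta_path}: metadata missing columns {missing}")
    else:
        meta = pd.DataFrame(
            {"patient": list(df.columns), "phase": "primary"},
            index=pd.Index(df.columns, name="sample"),
        )
    return ExpressionMatrix(df, meta, scale)


# -- pairing ----------------------------------------------------------------

def write_pairing_tsv(pairs: PairingTable, path) -> None:
    pairs.records.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_pairing_tsv(path) -> PairingTable:
    df = _read_tsv(path)
    req = {"patient", "primary_sample", "relapse_sample"}
    if not req.issubset(df.columns):
        raise ValueError(f"{path}: pairing table needs columns {sorted(req)}")
    return PairingTable(df)


# -- target-prediction resources -------------------------------------------

def write_resource_tsv(resources: list[TargetResource], path) -> None:
    rows = [
        {"resource": r.name, "mirna": m, "gene": g}
        for r in resources
        for m, g in sorted(r.edges)
    ]
    pd.DataFrame(rows, columns=["resource", "mirna", "gene"]).to_csv(
        path, sep="\t", index=False, encoding="utf-8"
    )


def read_resource_tsv(path) -> list[TargetResource]:
    df = _read_tsv(path)
    req = {"resource", "mirna", "gene"}
    if not req.issubset(df.columns):
        raise ValueError(f"{path}: resource table needs columns {sorted(req)}")
    out = []
    for name, grp in df.groupby("resource", sort=True):
        edges = set(zip(grp["mirna"], grp["gene"]))
        out.append(TargetResource(name=str(name), edges=edges))
    return out


# -- GMT gene sets ----------------------------------------------------------

def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(collection.sets):
            desc = collection.descriptions.get(name, "na")
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


def read_gmt(path, universe=None) -> GeneSetCollection:
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT line needs >= 3 tab-separated "
                    f"fields (name, description, members), got {len(fields)}"
                )
            name, desc, *members = fields
            if name in sets:
                raise ValueError(f"{path}: line {lineno}: duplicate set name {name!r}")
            sets[name] = set(members)
            descriptions[name] = desc
    if universe is None:
        universe = set().union(*sets.values()) if sets else set()
    return GeneSetCollection(sets=sets, universe=set(universe), descriptions=descriptions)


# -- survival ---------------------------------------------------------------

def write_survival_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_survival_tsv(path) -> pd.DataFrame:
    df = _read_tsv(path)
    try:
        validate_survival_table(df)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc
    return df


# -- Ct tables --------------------------------------------------------------

def write_ct_tsv(ct: pd.DataFrame, path) -> None:
    ct.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_ct_tsv(path) -> pd.DataFrame:
    df = _read_tsv(path)
    try:
        validate_ct_table(df)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc
    return df


# -- derived tables ---------------------------------------------------------

def write_edge_list(pairs, path) -> None:
    """Simple miRNA->gene edge list for network visualization tools."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\trho\n")
        for p in pairs:
            fh.write(f"{p.mirna}\t{p.gene}\t{p.rho:.6g}\n")


def write_truth(truth, path) -> None:
    """Flat key = value serialization of a SimulationTruth."""
    with open(path, "w", encoding="utf-8") as fh:
        for key, val in truth.to_flat_dict().items():
            fh.write(f"{key} = {val}\n")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
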