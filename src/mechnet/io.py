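"""Readers and writers for the plain-text formats the pipeline touches.

Everything is tab-separated UTF-8 with '.' decimals: GMT gene sets, regulon
tables (tr, target, mode, likelihood), expression/activity matrices (first
column = row id), network edge lists, and sample-group assignments. Writers
emit floats at 6 significant digits and sort rows by id so output is
byte-deterministic.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import EDGE_COLUMNS, GeneSet, MechanismNetwork, Regulon

logger = logging.getLogger(__name__)

__all__ = ["read_gmt", "write_gmt", "read_regulons", "write_regulons",
           "read_expression", "write_expression", "read_activity", "write_activity",
           "read_network", "write_network", "read_groups", "write_groups"]

_FLOAT_FMT = "%.6g"


class ParseError(ValueError):
    """Malformed input file; the message carries the file and line number."""


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path) -> list[GeneSet]:
    """Parse a GMT file: name, description, then one gene per field."""
    genesets = []
    with open(path, encoding="utf8", newline=None) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs >= 3 fields "
                                 f"(name, description, genes...), got {len(fields)}")
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            unique = list(dict.fromkeys(genes))
            if len(unique) != len(genes):
                logger.warning("%s:%d: %d duplicate gene(s) in set %s dropped",
                               path, lineno, len(genes) - len(unique), name)
            genesets.append(GeneSet(name, frozenset(unique)))
    if not genesets:
        raise ParseError(f"{path}: no gene sets found")
    return genesets


def write_gmt(genesets: list[GeneSet], path) -> None:
    with open(path, "w", encoding="utf8") as fh:
        for gs in sorted(genesets, key=lambda g: g.name):
            fh.write("\t".join([gs.name, "na", *sorted(gs.genes)]) + "\n")


# ---------------------------------------------------------------------------
# regulons


def read_regulons(path) -> list[Regulon]:
    """Parse a regulon TSV with columns tr, target, mode[, likelihood]."""
    df = pd.read_csv(path, sep="\t")
    required = {"tr", "target", "mode"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: regulon table needs columns {sorted(required)}")
    if "likelihood" not in df.columns:
        df["likelihood"] = 1.0
    bad = ~df["mode"].between(-1, 1) | ~np.isfinite(df["mode"])
    if bad.any():
        row = int(np.where(bad)[0][0]) + 2  # +1 header, +1 one-based
        raise ParseError(f"{path}:{row}: mode outside [-1, 1]")
    regulons = []
    for tr, sub in df.groupby("tr", sort=True):
        regulons.append(Regulon(tr_id=str(tr),
                                targets=sub["target"].astype(str).to_numpy(dtype=object),
                                modes=sub["mode"].to_numpy(dtype=float),
                                likelihoods=sub["likelihood"].to_numpy(dtype=float)))
    return regulons


def write_regulons(regulons: list[Regulon], path) -> None:
    rows = []
    for reg in sorted(regulons, key=lambda r: r.tr_id):
        order = np.argsort(reg.targets.astype(str))
        for i in order:
            rows.append((reg.tr_id, reg.targets[i], reg.modes[i], reg.likelihoods[i]))
    pd.DataFrame(rows, columns=["tr", "target", "mode", "likelihood"]) \
        .to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# matrices


def _read_matrix(path, kind: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ParseError(f"{path}: empty {kind} matrix")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate row ids {dups[:5]}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate column ids {dups[:5]}")
    df.index = df.index.astype(str)
    df.index.name = None  # the header label ("gene"/"mechanism") is cosmetic
    return df


def read_expression(path) -> pd.DataFrame:
    """Genes x samples TSV, gene ids in the first column."""
    return _read_matrix(path, "expression")


def write_expression(expr: pd.DataFrame, path) -> None:
    if expr.shape[0] == 0 or expr.shape[1] == 0:
        raise ValueError("refusing to write an empty expression matrix")
    expr.sort_index().to_csv(path, sep="\t", index_label="gene",
                             float_format=_FLOAT_FMT)


def read_activity(path) -> pd.DataFrame:
    """Mechanisms x samples NES matrix."""
    return _read_matrix(path, "activity")


def write_activity(acts: pd.DataFrame, path) -> None:
    if acts.shape[0] == 0 or acts.shape[1] == 0:
        raise ValueError("refusing to write an empty activity matrix")
    acts.sort_index().to_csv(path, sep="\t", index_label="mechanism",
                             float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# networks


def write_network(net: MechanismNetwork, path) -> None:
    edges = net.edges.loc[:, EDGE_COLUMNS].sort_values(["pathway", "tr"], kind="stable")
    edges.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT, na_rep="")


def read_network(path) -> MechanismNetwork:
    """Edge-list TSV back into a network (node lists = edge endpoints)."""
    edges = pd.read_csv(path, sep="\t")
    missing = set(EDGE_COLUMNS) - {"weight"} - set(edges.columns)
    if missing:
        raise ParseError(f"{path}: missing edge columns {sorted(missing)}")
    if "weight" not in edges.columns:
        edges["weight"] = np.nan
    edges["tr"] = edges["tr"].astype(str)
    edges["pathway"] = edges["pathway"].astype(str)
    return MechanismNetwork(edges=edges[EDGE_COLUMNS],
                            tr_ids=sorted(set(edges["tr"])),
                            pathway_ids=sorted(set(edges["pathway"])))


# ---------------------------------------------------------------------------
# sample groups


def read_groups(path) -> pd.Series:
    """Sample-to-group assignment TSV with columns sample, group."""
    df = pd.read_csv(path, sep="\t")
    if not {"sample", "group"}.issubset(df.columns):
        raise ParseError(f"{path}: group table needs columns sample, group")
    if df["sample"].duplicated().any():
        raise ParseError(f"{path}: duplicate sample ids")
    return pd.Series(df["group"].astype(str).to_numpy(),
                     index=df["sample"].astype(str), name="group")


def write_groups(groups: pd.Series, path) -> None:
    pd.DataFrame({"sample": groups.index.astype(str), "group": groups.to_numpy()}) \
        .sort_values("sample").to_csv(path, sep="\t", index=False)
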