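"""Readers and writers for the pipeline's standard artifacts.

All tabular artifacts are TSV. Omics matrices are stored with features as
rows and samples as columns (the usual convention for proteomics result
tables); in memory they are held as sample x feature :class:`pandas.DataFrame`
objects inside :class:`OmicsMatrix`. Interaction networks are 3-column edge
lists, gene sets are GMT, model results and ground truth are JSON.

Readers validate strictly and raise :class:`FormatError` rather than coerce;
every writer produces a file its paired reader accepts.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MODALITIES = ("mutation", "transcript", "protein", "phosphosite")

#: phosphosite ids look like "GENE-pS123": parent gene, residue (S/T/Y), position
_SITE_RE = re.compile(r"^(?P<gene>.+)-p(?P<residue>[STY])(?P<position>\d+)$")


class FormatError(ValueError):
    """Raised when a file or in-memory table violates a format invariant."""


def parse_site_id(site_id: str) -> tuple[str, str, int]:
    """Split a phosphosite id of the form ``GENE-pS123`` into its parts.

    Returns ``(gene, residue, position)``; raises :class:`FormatError` when
    the id does not parse.
    """
    m = _SITE_RE.match(site_id)
    if m is None:
        raise FormatError(f"phosphosite id {site_id!r} does not match 'GENE-pS123' form")
    return m.group("gene"), m.group("residue"), int(m.group("position"))


def site_parent_gene(site_id: str) -> str:
    """Parent gene of a phosphosite id."""
    return parse_site_id(site_id)[0]


@dataclass
class OmicsMatrix:
    """A sample x feature matrix for one molecular modality.

    mutations are strictly binary 0/1; transcripts are nonnegative CPM;
    proteins and phosphosites are log2 ratios against a common reference
    and may be any real value.
    """

    modality: str
    values: pd.DataFrame  # index: sample ids, columns: feature ids

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise FormatError(f"unknown modality {self.modality!r}; expected one of {MODALITIES}")
        v = self.values
        if v.index.duplicated().any():
            dups = v.index[v.index.duplicated()].tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        if v.columns.duplicated().any():
            dups = v.columns[v.columns.duplicated()].tolist()
            raise FormatError(f"duplicate feature ids: {dups}")
        arr = v.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise FormatError(f"{self.modality} matrix contains non-numeric values")
        if self.modality == "mutation":
            ok = np.isin(arr[~np.isnan(arr.astype(float))], (0.0, 1.0))
            if arr.size and not ok.all():
                raise FormatError("mutation matrix must contain only 0 and 1")
        if self.modality == "transcript":
            with np.errstate(invalid="ignore"):
                if arr.size and np.nanmin(arr.astype(float)) < 0:
                    raise FormatError("transcript (CPM) matrix must be nonnegative")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def features(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class DrugResponseTable:
    """Drug x sample AUC table; the regression response. NaN marks a drug
    not assayed on a sample. AUC is area under the dose-response viability
    curve: low = sensitive, high = resistant."""

    auc: pd.DataFrame  # index: drug ids, columns: sample ids

    def __post_init__(self) -> None:
        a = self.auc
        if a.index.duplicated().any():
            raise FormatError("duplicate drug ids in response table")
        if a.columns.duplicated().any():
            raise FormatError("duplicate sample ids in response table")
        arr = a.to_numpy(dtype=float)
        present = ~np.isnan(arr)
        if arr.size and np.isinf(arr[present]).any():
            raise FormatError("AUC values must be finite where present")
        if arr.size and present.any() and (arr[present] < 0).any():
            raise FormatError("AUC values must be nonnegative")

    @property
    def drugs(self) -> list[str]:
        return list(self.auc.index)

    @property
    def samples(self) -> list[str]:
        return list(self.auc.columns)


@dataclass
class MultiOmicCohort:
    """The four per-modality matrices of one cohort, sharing a sample index."""

    matrices: dict[str, OmicsMatrix] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, m in self.matrices.items():
            if name != m.modality:
                raise FormatError(f"matrix stored under {name!r} has modality {m.modality!r}")

    def __getitem__(self, modality: str) -> OmicsMatrix:
        return self.matrices[modality]

    def __contains__(self, modality: str) -> bool:
        return modality in self.matrices

    @property
    def modalities(self) -> list[str]:
        return [m for m in MODALITIES if m in self.matrices]

    @property
    def samples(self) -> list[str]:
        mods = self.modalities
        if not mods:
            return []
        common = set(self.matrices[mods[0]].samples)
        for m in mods[1:]:
            common &= set(self.matrices[m].samples)
        # preserve the order of the first matrix
        return [s for s in self.matrices[mods[0]].samples if s in common]


@dataclass
class PPIEdgeList:
    """Undirected protein-protein interactions with confidences in (0,1)."""

    edges: pd.DataFrame  # columns: node_a, node_b, confidence

    def __post_init__(self) -> None:
        e = self.edges
        required = ["node_a", "node_b", "confidence"]
        if list(e.columns[:3]) != required:
            raise FormatError(f"edge list must have columns {required}")
        if (e["node_a"] == e["node_b"]).any():
            bad = e.loc[e["node_a"] == e["node_b"]].index[0]
            raise FormatError(f"self-loop at row {bad}")
        conf = e["confidence"].to_numpy(dtype=float)
        if conf.size and ((conf <= 0) | (conf >= 1)).any():
            raise FormatError("edge confidences must lie strictly in (0, 1)")

    @property
    def nodes(self) -> set[str]:
        return set(self.edges["node_a"]) | set(self.edges["node_b"])


@dataclass
class KinaseSubstrateMap:
    """Kinase gene -> phosphosite annotations."""

    pairs: pd.DataFrame  # columns: kinase, site

    def __post_init__(self) -> None:
        p = self.pairs
        if list(p.columns[:2]) != ["kinase", "site"]:
            raise FormatError("kinase-substrate map must have columns ['kinase', 'site']")
        for s in p["site"]:
            parse_site_id(s)  # raises on malformed ids

    def kinases_of(self, site_id: str) -> list[str]:
        sel = self.pairs.loc[self.pairs["site"] == site_id, "kinase"]
        return sorted(set(sel))

    def sites_of(self, kinase: str) -> list[str]:
        sel = self.pairs.loc[self.pairs["kinase"] == kinase, "site"]
        return sorted(set(sel))


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics)."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


# ---------------------------------------------------------------------------
# matrices


def read_matrix(path, modality: str) -> OmicsMatrix:
    """Read a feature x sample TSV into an :class:`OmicsMatrix`.

    The header row carries the sample ids; the first column the feature ids.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce")
        nonnum = bad.isna() & df[col].notna()
        if nonnum.any():
            line = int(np.flatnonzero(nonnum.to_numpy())[0]) + 2  # +1 header, +1 1-based
            raise FormatError(f"{path}: non-numeric cell in column {col!r} at line {line}")
        df[col] = bad
    df.index = df.index.astype(str).rename(None)
    df.columns = df.columns.astype(str)
    return OmicsMatrix(modality=modality, values=df.T)


def write_matrix(matrix: OmicsMatrix, path) -> None:
    matrix.values.T.to_csv(path, sep="\t", index_label="feature")


def read_drug_response(path) -> DrugResponseTable:
    """Read a drug x sample AUC TSV (drugs as rows)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return DrugResponseTable(auc=df.astype(float))


def write_drug_response(table: DrugResponseTable, path) -> None:
    table.auc.to_csv(path, sep="\t", index_label="drug")


# ---------------------------------------------------------------------------
# networks, annotations


def read_edgelist(path) -> PPIEdgeList:
    """Read a 3-column TSV edge list; duplicate edges (either orientation)
    collapse to one keeping the maximum confidence."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise FormatError(f"{path}: expected 3 columns (node_a, node_b, confidence)")
    df = df.iloc[:, :3]
    df.columns = ["node_a", "node_b", "confidence"]
    df["node_a"] = df["node_a"].astype(str)
    df["node_b"] = df["node_b"].astype(str)
    df["confidence"] = pd.to_numeric(df["confidence"], errors="raise")
    key = df.apply(lambda r: tuple(sorted((r["node_a"], r["node_b"]))), axis=1)
    df = df.assign(_key=key)
    df = df.sort_values("confidence").drop_duplicates("_key", keep="last")
    df = df.drop(columns="_key").reset_index(drop=True)
    return PPIEdgeList(edges=df)


def write_edgelist(ppi: PPIEdgeList, path) -> None:
    ppi.edges.to_csv(path, sep="\t", index=False)


def read_ks(path) -> KinaseSubstrateMap:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected 2 columns (kinase, site)")
    df = df.iloc[:, :2]
    df.columns = ["kinase", "site"]
    df = df.astype(str).drop_duplicates().reset_index(drop=True)
    return KinaseSubstrateMap(pairs=df)


def write_ks(ks: KinaseSubstrateMap, path) -> None:
    ks.pairs.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> GeneSetCollection:
    """Read GMT: name <tab> description <tab> member1 <tab> member2 ...

    Lines with zero members are skipped with a warning.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3 or all(not p for p in parts[2:]):
                warnings.warn(f"{path}:{lineno}: gene set {parts[0]!r} has no members; skipped")
                continue
            name, desc = parts[0], parts[1]
            members = [p for p in parts[2:] if p]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")
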