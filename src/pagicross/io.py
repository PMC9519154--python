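"""Core containers and plain-text readers/writers.

All pipeline artifacts are tab-separated text (counts, phenotypes, survival,
pathway edges), GMT gene sets, one-symbol-per-line gene lists and JSON, so a
run directory is fully inspectable with standard command-line tools.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

FLOAT_FMT = "%.10g"


class DataError(ValueError):
    """Raised when an input violates a container invariant."""


@dataclass
class CountMatrix:
    """Integer count matrix (genes x samples) with per-sample phenotype.

    ``pheno`` is indexed by sample id and carries at least ``group``
    (values ``AD``/``control``) and ``batch`` columns.
    """

    counts: pd.DataFrame
    pheno: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise DataError("duplicate gene ids in count matrix")
        if self.counts.columns.duplicated().any():
            raise DataError("duplicate sample ids in count matrix")
        if not self.counts.columns.equals(self.pheno.index):
            self.pheno = self.pheno.loc[self.counts.columns]
        if "group" not in self.pheno.columns:
            raise DataError("pheno table must carry a 'group' column")
        if (self.counts.to_numpy() < 0).any():
            raise DataError("counts must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def group_mask(self, group: str = "AD"):
        return (self.pheno["group"] == group).to_numpy()

    def subset_genes(self, genes) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(genes)], self.pheno.copy())


@dataclass
class Pathway:
    id: str
    name: str
    genes: set[str]
    edges: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a not in self.genes or b not in self.genes:
                raise DataError(
                    f"pathway {self.id}: edge ({a},{b}) has non-member endpoint"
                )


@dataclass
class PathwayCollection:
    pathways: list[Pathway]

    def __post_init__(self) -> None:
        ids = [p.id for p in self.pathways]
        if len(ids) != len(set(ids)):
            raise DataError("duplicate pathway ids")

    def __iter__(self):
        return iter(self.pathways)

    def __len__(self) -> int:
        return len(self.pathways)

    def __getitem__(self, pid: str) -> Pathway:
        for p in self.pathways:
            if p.id == pid:
                return p
        raise KeyError(pid)

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.pathways]

    def gene_universe(self) -> set[str]:
        out: set[str] = set()
        for p in self.pathways:
            out |= p.genes
        return out


# ---------------------------------------------------------------------------
# readers / writers


def write_counts(m: CountMatrix, counts_path: Path, pheno_path: Path | None = None) -> None:
    df = m.counts.copy()
    df.index.name = "gene"
    df.to_csv(counts_path, sep="\t")
    if pheno_path is not None:
        ph = m.pheno.copy()
        ph.index.name = "sample"
        ph.to_csv(pheno_path, sep="\t")


def read_counts(counts_path: Path, pheno_path: Path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    pheno = pd.read_csv(pheno_path, sep="\t", index_col=0)
    pheno.index = pheno.index.astype(str)
    counts.columns = counts.columns.astype(str)
    return CountMatrix(counts, pheno)


def write_matrix(df: pd.DataFrame, path: Path, index_name: str = "gene") -> None:
    out = df.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_matrix(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = df.columns.astype(str)
    return df


def write_gmt(pc: PathwayCollection, path: Path) -> None:
    with open(path, "w") as fh:
        for p in pc:
            genes = "\t".join(sorted(p.genes))
            fh.write(f"{p.id}\t{p.name}\t{genes}\n")


def read_gmt(path: Path) -> list[Pathway]:
    out = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out.append(Pathway(parts[0], parts[1], set(parts[2:])))
    return out


def write_edges(pc: PathwayCollection, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("pathway_id\tgene_a\tgene_b\n")
        for p in pc:
            for a, b in sorted(tuple(sorted(e)) for e in p.edges):
                fh.write(f"{p.id}\t{a}\t{b}\n")


def read_pathways(gmt_path: Path, edges_path: Path) -> PathwayCollection:
    pathways = {p.id: p for p in read_gmt(gmt_path)}
    edges = pd.read_csv(edges_path, sep="\t")
    for row in edges.itertuples(index=False):
        pw = pathways.get(str(row.pathway_id))
        if pw is None:
            raise DataError(f"edge refers to unknown pathway {row.pathway_id}")
        pw.edges.append((str(row.gene_a), str(row.gene_b)))
    # re-validate edge endpoints
    return PathwayCollection([Pathway(p.id, p.name, p.genes, p.edges)
                              for p in pathways.values()])


def write_gene_list(genes, path: Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_gene_list(path: Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_lengths(lengths: pd.Series, path: Path) -> None:
    df = lengths.rename("length").to_frame()
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


def read_gene_lengths(path: Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df["length"]


def write_survival(df: pd.DataFrame, path: Path) -> None:
    out = df.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_survival(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_json(path: Path):
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, set):
        return sorted(obj)
    if hasattr(obj, "item"):
        return obj.item()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
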