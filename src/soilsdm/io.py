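"""Readers and writers for the plain-text interchange formats.

Count tables are TSV with taxa in rows and sites in columns (leading id
column); environmental and resurvey tables are CSV with a header row;
similarity matrices are square TSV with the id header duplicated on rows and
columns; sequences are FASTA.  Floats are written at full precision, so a
write/read round trip is exact for integers and far beyond 12 significant
digits for reals.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import SimilarityScores, ZOtuTable, OtuTable


def _check_unique(index: pd.Index, what: str, path) -> None:
    if index.has_duplicates:
        dup = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} ids in {path}: {dup}")


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="id")


def read_counts_tsv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:  # pandas reports the offending line
        raise ValueError(f"malformed count table {path}: {exc}") from exc
    _check_unique(df.index, "taxon", path)
    _check_unique(df.columns, "site", path)
    bad = df.columns[~df.apply(lambda c: np.issubdtype(c.dtype, np.number))]
    if len(bad):
        raise ValueError(f"non-numeric count columns in {path}: {list(bad)}")
    df.index.name = None
    return df.astype(np.int64)


def write_env_csv(env: pd.DataFrame, path) -> None:
    env.to_csv(path, index_label="site")


def read_env_csv(path, schema=None) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed environmental table {path}: {exc}") from exc
    _check_unique(df.index, "site", path)
    if schema is not None:
        from .containers import validate_env

        validate_env(df, schema)
        df = df[list(schema.names)]
    return df


def write_series_tsv(series: pd.Series, path, name: str | None = None) -> None:
    series.rename(name or series.name or "value").to_csv(path, sep="\t", index_label="id")


def read_series_tsv(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    _check_unique(df.index, "row", path)
    return df.iloc[:, 0]


def write_similarity_tsv(sim: SimilarityScores, path) -> None:
    pd.DataFrame(sim.sim, index=list(sim.ids), columns=list(sim.ids)).to_csv(
        path, sep="\t", index_label="id"
    )


def read_similarity_tsv(path) -> SimilarityScores:
    df = pd.read_csv(path, sep="\t", index_col=0)
    _check_unique(df.index, "sequence", path)
    if list(df.index) != list(df.columns):
        raise ValueError(f"similarity table {path} must have matching row/column ids")
    return SimilarityScores(ids=tuple(df.index), sim=df.to_numpy(dtype=float))


def write_fasta(records, path) -> None:
    seen = set()
    with open(path, "w") as fh:
        for rid, seq in records:
            if rid in seen:
                raise ValueError(f"duplicate sequence id {rid!r}")
            seen.add(rid)
            fh.write(f">{rid}\n{seq}\n")


def read_fasta(path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    records, seen = [], set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq)))
    return records


def write_cluster_map(members: dict[str, list[str]], path) -> None:
    rows = [(z, otu) for otu, zs in members.items() for z in zs]
    pd.DataFrame(rows, columns=["zotu", "otu"]).to_csv(path, sep="\t", index=False)


def read_cluster_map(path) -> dict[str, list[str]]:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != ["zotu", "otu"]:
        raise ValueError(f"cluster map {path} must have columns (zotu, otu)")
    _check_unique(pd.Index(df["zotu"]), "zotu", path)
    out: dict[str, list[str]] = {}
    for z, o in zip(df["zotu"], df["otu"]):
        out.setdefault(o, []).append(z)
    return out


def write_zotu_table(zotus: ZOtuTable, counts_path, taxonomy_path, library_path) -> None:
    write_counts_tsv(zotus.counts, counts_path)
    write_series_tsv(zotus.taxonomy, taxonomy_path, name="phylum")
    write_series_tsv(zotus.library_sizes, library_path, name="library_size")


def read_zotu_table(counts_path, taxonomy_path, library_path) -> ZOtuTable:
    return ZOtuTable(
        counts=read_counts_tsv(counts_path),
        taxonomy=read_series_tsv(taxonomy_path),
        library_sizes=read_series_tsv(library_path).astype(np.int64),
    )


def write_otu_table(otus: OtuTable, prefix: Path) -> None:
    prefix = Path(prefix)
    write_counts_tsv(otus.counts, prefix.with_suffix(".counts.tsv"))
    write_series_tsv(otus.phylum, prefix.with_suffix(".phylum.tsv"), name="phylum")
    write_series_tsv(otus.library_sizes, prefix.with_suffix(".lib.tsv"), name="library_size")
    write_cluster_map(otus.members, prefix.with_suffix(".members.tsv"))


def read_otu_table(prefix: Path) -> OtuTable:
    prefix = Path(prefix)
    return OtuTable(
        counts=read_counts_tsv(prefix.with_suffix(".counts.tsv")),
        phylum=read_series_tsv(prefix.with_suffix(".phylum.tsv")),
        library_sizes=read_series_tsv(prefix.with_suffix(".lib.tsv")).astype(np.int64),
        members=read_cluster_map(prefix.with_suffix(".members.tsv")),
    )


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


__all__ = [n for n in dir() if n.startswith(("read_", "write_"))]
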