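"""Readers and writers for the plain-text formats the pipeline speaks.

Dialect: tab-delimited UTF-8, '.' decimal, no quoting; lines starting with
'#' are comments.  Gene identifiers are opaque case-sensitive strings; no
identifier mapping is attempted.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from .enrichment import GeneSet, GeneSetCollection
from .network import GeneNetwork, SeedSet, build_network

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


def _data_lines(path):
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_edge_list(path) -> GeneNetwork:
    """Read a 2-column TSV edge list or a 3-column SIF file.

    SIF's middle relation column is ignored.
    """
    records = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) == 2:
            records.append((fields[0], fields[1]))
        elif len(fields) == 3:  # SIF: a relation b
            records.append((fields[0], fields[2]))
        else:
            raise ValueError(
                f"{path}:{lineno}: expected 2 (TSV) or 3 (SIF) columns, "
                f"got {len(fields)}")
    return build_network(records)


def write_edge_list(net: GeneNetwork, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in net.edges):
            fh.write(f"{a}\t{b}\n")


def read_seeds(path) -> SeedSet:
    genes = [line.strip() for _, line in _data_lines(path)]
    if not genes:
        raise ValueError(f"no seed genes in {path}")
    return SeedSet(genes=tuple(dict.fromkeys(genes)))


def parse_gmt(path) -> GeneSetCollection:
    """Read a GMT file: name TAB description TAB member genes."""
    sets = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
        name, desc = fields[0], fields[1]
        members = [g for g in fields[2:] if g.strip()]
        uniq = set(members)
        if len(uniq) < len(members):
            logger.info("%s:%d: %d duplicate member(s) dropped in %s",
                        path, lineno, len(members) - len(uniq), name)
        sets.append(GeneSet(name=name, description=desc,
                            genes=frozenset(uniq)))
    return GeneSetCollection(sets=tuple(sets))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.genes)]))
            fh.write("\n")


def parse_matrix(path) -> pd.DataFrame:
    """Read a genes-by-samples numeric TSV (header = sample ids).

    Duplicate gene rows are collapsed by mean with a warning; ragged rows
    and non-numeric cells raise.
    """
    header: list[str] | None = None
    rows, index = [], []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if header is None:
            header = fields[1:]
            continue
        if len(fields) != len(header) + 1:
            raise ValueError(f"{path}:{lineno}: ragged row "
                             f"({len(fields)} fields, expected {len(header) + 1})")
        try:
            rows.append([float(v) for v in fields[1:]])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric cell ({exc})") from exc
        index.append(fields[0])
    if header is None:
        raise ValueError(f"{path}: empty matrix file")
    df = pd.DataFrame(rows, index=index, columns=header)
    if df.index.has_duplicates:
        n_dup = len(df) - df.index.nunique()
        logger.warning("%s: %d duplicate gene row(s) collapsed by mean",
                       path, n_dup)
        df = df.groupby(level=0, sort=False).mean()
    return df


def write_matrix(df: pd.DataFrame, path, index_name: str = "gene") -> None:
    df.to_csv(path, sep="\t", index_label=index_name)


def read_two_column(path, names=("key", "value")) -> pd.DataFrame:
    """Read a 2+-column TSV (e.g. gene lengths, immune scores, mutations,
    drug targets, response labels); a header row is detected when the
    second field of the first line is non-numeric and matches no data."""
    rows = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < len(names):
            raise ValueError(f"{path}:{lineno}: expected >= {len(names)} columns")
        rows.append(fields[:max(len(names), len(fields))])
    if not rows:
        raise ValueError(f"{path}: empty table")
    if rows[0][0].strip().lower() == names[0].lower():
        rows = rows[1:]
        if not rows:
            raise ValueError(f"{path}: header only, no data rows")
    width = max(len(names), min(len(r) for r in rows)) if rows else len(names)
    cols = list(names) + [f"col{i}" for i in range(len(names), width)]
    return pd.DataFrame([r[:width] for r in rows], columns=cols)


def read_config(path) -> dict:
    """Plain-text key = value configuration ('#' comments allowed)."""
    cfg = {}
    for lineno, line in _data_lines(path):
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        cfg[key.strip()] = value.strip()
    return cfg


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, command: str, params: dict,
                   input_files: dict) -> Path:
    """Emit the JSON run manifest (parameters + input checksums)."""
    manifest = {
        "command": command,
        "parameters": params,
        "inputs": {name: {"path": str(p), "sha256": file_checksum(p)}
                   for name, p in input_files.items() if p is not None},
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    out = Path(out_dir) / "manifest.json"
    out.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
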