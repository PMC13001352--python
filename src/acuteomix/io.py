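"""Readers and writers for the plain-text interchange formats.

Matrices travel as TSV (features x samples, first column = feature id),
peaks as BED (0-based half-open), gene sets as GMT, annotation as a
GTF-like TSV, and the synthetic truth as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .core import OmicsMatrix


def read_matrix_tsv(path, ome: str) -> OmicsMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    return OmicsMatrix(values, ome)


def write_matrix_tsv(m: OmicsMatrix, path) -> None:
    m.values.to_csv(path, sep="\t", index_label="feature_id")


def read_design_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"batch": str})


def write_design_tsv(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_bed(path) -> pd.DataFrame:
    """Read a BED file of peaks: chrom, start, end, name."""
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name"], usecols=[0, 1, 2, 3],
    )
    return df


def write_bed(peaks: pd.DataFrame, path) -> None:
    peaks[["chrom", "start", "end", "name"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_gmt(path) -> dict:
    """Read GMT gene sets.

    Members of directional PTM signatures are encoded as ``id;u`` / ``id;d``
    and returned as (id, direction) tuples; plain members come back as str.
    """
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, _desc, *members = parts
            parsed = []
            for mem in members:
                if not mem:
                    continue
                if mem.endswith(";u") or mem.endswith(";d"):
                    parsed.append((mem[:-2], mem[-1]))
                else:
                    parsed.append(mem)
            sets[name] = parsed
    return sets


def write_gmt(sets: dict, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            encoded = [
                f"{m[0]};{m[1]}" if isinstance(m, tuple) else str(m)
                for m in members
            ]
            fh.write("\t".join([name, description, *encoded]) + "\n")


def read_annotation_tsv(path) -> pd.DataFrame:
    """GTF-like gene annotation: gene_id, chrom, tss, strand."""
    return pd.read_csv(path, sep="\t")


def write_annotation_tsv(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, sep="\t", index=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


def read_json(path):
    return json.loads(Path(path).read_text())
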