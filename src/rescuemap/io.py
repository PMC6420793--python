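"""Readers and writers for the on-disk formats the pipeline consumes.

Counts are TSV (gene-id first column, sample header) or MatrixMarket with
sidecar id files; genes and elements travel as BED6-style 0-based half-open
records; sequence as FASTA wrapped at 80 columns.  All writers emit a fixed
column order, ``\\n`` line endings and a fixed float format so that reruns
on identical inputs are byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_counts", "write_counts", "read_samples", "write_tsv",
    "read_bed", "write_bed", "read_fasta", "write_fasta",
    "read_config", "write_config",
]

FLOAT_FORMAT = "%.10g"


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT,
              lineterminator="\n")


def read_counts(path) -> pd.DataFrame:
    """Counts from TSV (gene rows, sample columns) or MatrixMarket.

    A ``.mtx`` file expects sidecars ``<stem>.genes.txt`` and
    ``<stem>.samples.txt`` with one id per line.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread

        mat = np.asarray(mmread(path).todense())
        genes = Path(path.with_suffix("")).with_suffix(".genes.txt").read_text().split()
        samples = Path(path.with_suffix("")).with_suffix(".samples.txt").read_text().split()
        counts = pd.DataFrame(mat, index=genes, columns=samples)
    else:
        counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index.name = "gene"
    if counts.index.has_duplicates:
        raise ValueError(f"duplicate gene ids in {path}")
    if counts.columns.has_duplicates:
        raise ValueError(f"duplicate sample ids in {path}")
    return counts.astype(np.int64)


def write_counts(counts: pd.DataFrame, path) -> None:
    write_tsv(counts.rename_axis("gene"), path, index=True)


def read_samples(path) -> pd.DataFrame:
    samples = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "condition", "batch"}
    if not required <= set(samples.columns):
        raise ValueError(f"sample sheet needs columns {sorted(required)}")
    if samples["sample"].duplicated().any():
        raise ValueError(f"duplicate sample ids in {path}")
    return samples


def read_bed(path) -> pd.DataFrame:
    """BED6 records as a DataFrame (0-based half-open; name in column 4)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: BED line has < 4 fields")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            score = parts[4] if len(parts) > 4 else "0"
            strand = parts[5] if len(parts) > 5 else "."
            rows.append((chrom, start, end, name, score, strand, parts[6:]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                       "score", "strand", "extra"])


def write_bed(df: pd.DataFrame, path, extra_cols: tuple = ()) -> None:
    """Write BED6 (+ optional extra columns) from a DataFrame.

    ``df`` needs chrom/start/end plus a name column (``name``, ``gene`` or
    ``element_id``).
    """
    name_col = next(c for c in ("name", "gene", "element_id") if c in df.columns)
    with open(path, "w") as fh:
        for rec in df.itertuples(index=False):
            d = rec._asdict()
            extras = "".join(f"\t{d[c]}" for c in extra_cols)
            strand = d.get("strand", ".")
            fh.write(f"{d['chrom']}\t{d['start']}\t{d['end']}\t{d[name_col]}"
                     f"\t0\t{strand}{extras}\n")


def genes_to_bed(genes: pd.DataFrame, path) -> None:
    """Gene TSS records as 1-bp BED6 intervals (0-based half-open)."""
    bed = genes.assign(start=genes["tss"], end=genes["tss"] + 1)
    write_bed(bed[["chrom", "start", "end", "gene", "strand"]], path)


def bed_to_genes(bed: pd.DataFrame) -> pd.DataFrame:
    """Interpret 1-bp BED intervals as TSS records."""
    return pd.DataFrame({"chrom": bed["chrom"], "tss": bed["start"],
                         "strand": bed["strand"], "gene": bed["name"]})


def read_fasta(path) -> dict[str, str]:
    """FASTA records as an ordered dict of id -> sequence."""
    records: dict[str, str] = {}
    current: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if line.startswith(">"):
                if current is not None:
                    records[current] = "".join(chunks)
                current = line[1:].split()[0] if len(line) > 1 else ""
                if not current:
                    raise ValueError(f"{path}: blank FASTA id at record {len(records)}")
                if current in records:
                    raise ValueError(f"{path}: duplicate FASTA id {current!r}")
                chunks = []
            elif line:
                if current is None:
                    raise ValueError(f"{path}: sequence before any header (line {i+1})")
                chunks.append(line)
    if current is not None:
        records[current] = "".join(chunks)
    return records


def write_fasta(records: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_config(path) -> dict:
    import json

    import yaml

    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def write_config(config: dict, path) -> None:
    import yaml

    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))
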