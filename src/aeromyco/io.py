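"""Readers and writers for the on-disk formats the pipeline touches.

Everything tabular is TSV (UTF-8, no quoting); sequences travel as FASTA
wrapped at 80 columns; taxonomic abundance hierarchies export in the Krona
text-import dialect.  Readers validate and reject rather than coerce:
unknown enumeration tokens, duplicate ids and out-of-range probabilities
are errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .levels import LEVELS

logger = logging.getLogger(__name__)

HABITATS = ("natural", "urban")
POSITIONS = ("core", "edge")
METHODS = ("air", "soil")

SAMPLE_COLUMNS = ["sample_id", "site", "plot", "habitat", "position", "method", "replicate"]
PLACEMENT_COLUMNS = ["read_id"] + [c for lv in LEVELS for c in (lv, f"p_{lv}")]

#: read ids follow "<sample_id><delimiter><read tag>"
READ_ID_DELIMITER = "|"

_VALID_CHARS = set("ACGTRYSWKMBDHVN")


@dataclass(frozen=True)
class SampleRecord:
    """Design metadata for one physical sample."""

    sample_id: str
    site: str
    plot: str
    habitat: str
    position: str
    method: str
    replicate: int


def sample_records(samples: pd.DataFrame) -> list[SampleRecord]:
    """Typed records from a validated sample table."""
    return [
        SampleRecord(
            sample_id=r.sample_id, site=r.site, plot=r.plot, habitat=r.habitat,
            position=r.position, method=r.method, replicate=int(r.replicate),
        )
        for r in samples.itertuples(index=False)
    ]


def read_fasta(path) -> tuple[list[str], list[str]]:
    """Read a FASTA file into (ids, uppercase sequences).

    Rejects duplicate ids, empty sequences, characters outside the IUPAC
    DNA alphabet, and files whose first record line is not a header.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{path}: malformed FASTA, line {lineno} is not a '>' header"
                    )
                break
        else:
            return [], []
    ids: list[str] = []
    seqs: list[str] = []
    seen: set[str] = set()
    with open(path) as fh:
        for header, seq in SimpleFastaParser(fh):
            rid = header.split()[0] if header.split() else ""
            if not rid:
                raise ValueError(f"{path}: record with empty id")
            if rid in seen:
                raise ValueError(f"{path}: duplicate sequence id {rid!r}")
            seen.add(rid)
            seq = seq.upper()
            if not seq:
                raise ValueError(f"{path}: empty sequence for id {rid!r}")
            bad = set(seq) - _VALID_CHARS
            if bad:
                raise ValueError(
                    f"{path}: invalid characters {sorted(bad)} in record {rid!r}"
                )
            ids.append(rid)
            seqs.append(seq)
    return ids, seqs


def write_fasta(records, path, wrap: int = 80) -> None:
    """Write (id, sequence) pairs as FASTA, uppercased, wrapped at 80 cols."""
    path = Path(path)
    seen: set[str] = set()
    with open(path, "w") as fh:
        for rid, seq in records:
            if rid in seen:
                raise ValueError(f"duplicate sequence id {rid!r}")
            seen.add(rid)
            seq = seq.upper()
            if not seq:
                raise ValueError(f"empty sequence for id {rid!r}")
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")


def read_sample_table(path) -> pd.DataFrame:
    """Read and validate the sample metadata TSV.

    Enumerated fields are accepted case-insensitively and stored lowercase;
    (site, plot, method, replicate) must be unique.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing sample columns {missing}")
    df = df[SAMPLE_COLUMNS].copy()
    for col, allowed in (("habitat", HABITATS), ("position", POSITIONS), ("method", METHODS)):
        df[col] = df[col].str.lower()
        bad = sorted(set(df[col]) - set(allowed))
        if bad:
            raise ValueError(f"{path}: unknown {col} value(s) {bad}; allowed {allowed}")
    df["replicate"] = df["replicate"].astype(int)
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{path}: duplicate sample ids {dups}")
    key = df[["site", "plot", "method", "replicate"]]
    if key.duplicated().any():
        raise ValueError(f"{path}: duplicate (site, plot, method, replicate) rows")
    return df


def read_placement_table(path) -> pd.DataFrame:
    """Read the per-read taxonomic placement TSV (PROTAX-style output)."""
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str})
    missing = [c for c in PLACEMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing placement columns {missing}")
    df = df[PLACEMENT_COLUMNS].copy()
    probs = df[[f"p_{lv}" for lv in LEVELS]].to_numpy(dtype=float)
    finite = probs[~np.isnan(probs)]
    if finite.size and (finite.max() > 1.0 or finite.min() < 0.0):
        raise ValueError(f"{path}: placement probabilities outside [0, 1]")
    if df["read_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate read ids in placements")
    return df


def read_tables(samples_path, placements_path, delimiter: str = READ_ID_DELIMITER):
    """Load sample metadata and placements together, checking integrity.

    Every placement read id must resolve, via the ``sample|read`` id
    convention, to a sample present in the metadata.
    """
    samples = read_sample_table(samples_path)
    placements = read_placement_table(placements_path)
    known = set(samples["sample_id"])
    sample_of = placements["read_id"].str.rsplit(delimiter, n=1).str[0]
    unknown = sorted(set(sample_of) - known)
    if unknown:
        raise ValueError(
            f"placements reference unknown samples {unknown[:5]}"
            + ("..." if len(unknown) > 5 else "")
        )
    placements = placements.assign(sample_id=sample_of)
    return samples, placements


def sample_of_read(read_id: str, delimiter: str = READ_ID_DELIMITER) -> str:
    """Sample id encoded in a read id."""
    return read_id.rsplit(delimiter, 1)[0]


def write_krona_text(table: pd.DataFrame, path, level_columns=None, abundance_column: str = "abundance") -> None:
    """Write a taxon abundance hierarchy in the Krona text-import dialect.

    One row per leaf: abundance, then the tab-separated taxonomic path.
    Negative abundances are an error; an empty table yields an empty file
    and a logged warning.
    """
    path = Path(path)
    if level_columns is None:
        level_columns = [lv for lv in LEVELS if lv in table.columns]
    if len(table) == 0:
        logger.warning("write_krona_text: empty table, writing empty file %s", path)
        path.write_text("")
        return
    ab = table[abundance_column].to_numpy(dtype=float)
    if (ab < 0).any():
        raise ValueError("write_krona_text: negative abundance")
    with open(path, "w") as fh:
        for _, row in table.iterrows():
            parts = [repr(float(row[abundance_column]))] + [
                str(row[c]) for c in level_columns if pd.notna(row[c])
            ]
            fh.write("\t".join(parts) + "\n")


def write_tsv(df: pd.DataFrame, path) -> None:
    """TSV writer used for every tabular artifact (UTF-8, no quoting)."""
    df.to_csv(path, sep="\t", index=False)
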