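"""Shared format I/O (FASTA, Stockholm, TSV) and run configuration.

Thin validated wrappers: FASTA and Stockholm go through Biopython, tables
through pandas.  Stockholm consensus structure (``#=GC SS_cons``, WUSS with
pseudoknot letter tiers) round-trips losslessly into the covariation module's
pair table.  All outputs are plain text.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .covariation import StructuredAlignment, pairs_to_wuss, parse_wuss
from .kinetics import TimeSeries, fraction_series

__all__ = [
    "RunConfig",
    "read_fasta",
    "write_fasta",
    "read_stockholm",
    "write_stockholm",
    "read_tsv",
    "write_tsv",
    "read_kinetics_tsv",
]

logger = logging.getLogger(__name__)


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> list[SeqRecord]:
    """All records of a (possibly gzipped) FASTA file; empty records rejected."""
    with _open_text(path) as fh:
        records = list(SeqIO.parse(fh, "fasta"))
    for idx, rec in enumerate(records):
        if len(rec.seq) == 0:
            raise ValueError(f"record {idx} ({rec.id!r}) has an empty sequence")
    return records


def write_fasta(records, path) -> None:
    """Write records (SeqRecord or (id, sequence) pairs) as FASTA."""
    recs = [
        r if isinstance(r, SeqRecord) else SeqRecord(Seq(r[1]), id=r[0], description="")
        for r in records
    ]
    with _open_text(path, "wt") as fh:
        SeqIO.write(recs, fh, "fasta")


def read_stockholm(path) -> StructuredAlignment:
    """Stockholm 1.0 with ``#=GC SS_cons`` into a StructuredAlignment."""
    with _open_text(path) as fh:
        aln = AlignIO.read(fh, "stockholm")
    ss = aln.column_annotations.get("secondary_structure")
    if ss is None:
        raise ValueError("Stockholm file lacks a #=GC SS_cons line")
    return StructuredAlignment(
        ids=tuple(r.id for r in aln),
        rows=tuple(str(r.seq) for r in aln),
        pairs=parse_wuss(ss),
    )


def write_stockholm(aln: StructuredAlignment, path) -> None:
    """Write a StructuredAlignment as Stockholm with reconstructed SS_cons."""
    msa = MultipleSeqAlignment(
        [SeqRecord(Seq(row), id=sid, description="") for sid, row in zip(aln.ids, aln.rows)]
    )
    msa.column_annotations["secondary_structure"] = pairs_to_wuss(
        aln.pairs, aln.n_cols
    )
    with _open_text(path, "wt") as fh:
        AlignIO.write(msa, fh, "stockholm")


def read_tsv(path, required: list[str] | None = None) -> pd.DataFrame:
    """Read a TSV table; missing required columns raise a named error."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"TSV {path} is missing column(s): {missing}")
    return df


def write_tsv(df: pd.DataFrame, path, header_lines: list[str] | None = None) -> None:
    with _open_text(path, "wt") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_kinetics_tsv(path) -> list[TimeSeries]:
    """Time courses from a TSV with columns construct, replicate, t_min, and
    either L and S band intensities or a precomputed fraction f."""
    df = read_tsv(path, required=["construct", "replicate", "t_min"])
    has_f = "f" in df.columns
    if not has_f and not {"L", "S"} <= set(df.columns):
        raise ValueError("kinetics TSV needs either an 'f' column or 'L' and 'S'")
    out = []
    for (construct, replicate), grp in df.groupby(["construct", "replicate"], sort=True):
        grp = grp.sort_values("t_min")
        if has_f:
            out.append(
                TimeSeries(
                    t=tuple(grp["t_min"].astype(float)),
                    f=tuple(grp["f"].astype(float)),
                    construct=str(construct),
                    replicate=str(replicate),
                )
            )
        else:
            out.append(
                fraction_series(
                    grp["L"].to_numpy(float),
                    grp["S"].to_numpy(float),
                    grp["t_min"].to_numpy(float),
                    construct=str(construct),
                    replicate=str(replicate),
                )
            )
    return out


@dataclass(frozen=True)
class RunConfig:
    """Run-wide configuration echoed into output headers."""

    seed: int = 0
    both_strands: bool = True
    cg_threshold: float = 0.15
    insertion_max_unstructured: int = 12
    min_supported_pairs: int = 3
    n_shuffles: int = 1000
    verbosity: str = "INFO"

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha1(payload).hexdigest()[:12]

    def header_lines(self) -> list[str]:
        return [
            f"config_hash={self.config_hash()}",
            f"seed={self.seed}",
        ] + [f"{k}={v}" for k, v in sorted(asdict(self).items()) if k != "seed"]
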