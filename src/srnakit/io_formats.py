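"""Readers and writers for every external format the pipeline touches.

All sequence data are normalized to the DNA alphabet on load (RNA ``U`` is
mapped to ``T``): sequencing reads are DNA, while mature-miRNA references
are usually distributed as RNA.  No science lives here.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("srnakit.io")

VALID_INPUT = set("ACGTUN")
DNA = set("ACGT")


class FormatError(ValueError):
    """Malformed or contract-violating input file."""


class ParseError(FormatError):
    """Low-level record parse failure; message names the offending position."""


@dataclass(slots=True)
class SmallRNARead:
    """A (possibly collapsed) small RNA sequence with multiplicity.

    ``count`` is the collapsed multiplicity; freshly loaded reads carry
    ``count=1``.  ``mean_quality`` is the mean Phred score when the read
    came from FASTQ, otherwise ``None``.
    """

    sequence: str
    count: int = 1
    tissue: str = ""
    mean_quality: float | None = None

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"read count must be >= 1, got {self.count}")

    def __len__(self) -> int:  # length of the sequence, in nt
        return len(self.sequence)


@dataclass(slots=True, frozen=True)
class MatureReference:
    """One mature miRNA reference entry (miRBase style).

    ``family`` is the identifier without its species prefix, e.g.
    ``dre-miR-1-3p`` -> ``miR-1-3p``.
    """

    id: str
    sequence: str
    family: str = field(default="")

    def __post_init__(self) -> None:
        if not self.family:
            object.__setattr__(self, "family", strip_species_prefix(self.id))
        if not 15 <= len(self.sequence) <= 30:
            raise FormatError(
                f"mature reference {self.id!r} has length {len(self.sequence)}; "
                "expected 15-30 nt"
            )
        bad = set(self.sequence) - DNA
        if bad:
            raise FormatError(f"reference {self.id!r} has non-ACGT characters {bad}")


def strip_species_prefix(ref_id: str) -> str:
    """Drop the three-letter species prefix of a miRBase-style identifier."""
    head, sep, tail = ref_id.partition("-")
    return tail if sep else ref_id


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _infer_format(path: str | Path) -> str:
    suffixes = [s.lower() for s in Path(path).suffixes if s != ".gz"]
    last = suffixes[-1] if suffixes else ""
    if last in {".fa", ".fasta", ".fna"}:
        return "fasta"
    if last in {".fq", ".fastq"}:
        return "fastq"
    raise FormatError(f"cannot infer sequence format from {path}")


def load_reads(
    path: str | Path,
    format: str | None = None,
    tissue: str = "",
) -> list[SmallRNARead]:
    """Load raw reads from FASTA/FASTQ into per-read records with count 1.

    ``U`` is mapped to ``T``; reads containing ``N`` are dropped and the
    dropped count is logged.  Any other character raises :class:`ParseError`.
    Order of the input records is preserved.
    """
    fmt = format or _infer_format(path)
    if fmt not in {"fasta", "fastq"}:
        raise ValueError(f"unsupported format {fmt!r}")
    reads: list[SmallRNARead] = []
    dropped = 0
    lines_per_record = 4 if fmt == "fastq" else 2
    with _open_text(path) as handle:
        records = SeqIO.parse(handle, fmt)
        index = 0
        while True:
            try:
                record = next(records)
            except StopIteration:
                break
            except ValueError as exc:
                raise ParseError(
                    f"{path}: malformed {fmt} record {index + 1} "
                    f"(near line {index * lines_per_record + 1}): {exc}"
                ) from exc
            seq = str(record.seq).upper().replace("U", "T")
            bad = set(seq) - DNA - {"N"}
            if bad:
                raise ParseError(
                    f"{path}: record {record.id!r} (record {index + 1}) contains "
                    f"invalid characters {sorted(bad)}"
                )
            if "N" in seq:
                dropped += 1
            else:
                quality = None
                if fmt == "fastq":
                    phred = record.letter_annotations.get("phred_quality", [])
                    quality = sum(phred) / len(phred) if phred else 0.0
                reads.append(
                    SmallRNARead(sequence=seq, count=1, tissue=tissue, mean_quality=quality)
                )
            index += 1
    logger.info(
        "loaded %d reads from %s (%d N-containing records dropped)",
        len(reads), path, dropped,
    )
    return reads


def load_reference(path: str | Path) -> list[MatureReference]:
    """Load a mature-miRNA reference FASTA; ``U`` -> ``T``, duplicate ids error.

    The FASTA header's first whitespace-separated token is the identifier.
    Duplicate sequences under different ids are both retained.
    """
    refs: list[MatureReference] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            if record.id in seen:
                raise FormatError(f"{path}: duplicate reference id {record.id!r}")
            seen.add(record.id)
            seq = str(record.seq).upper().replace("U", "T")
            refs.append(MatureReference(id=record.id, sequence=seq))
    logger.info("loaded %d mature references from %s", len(refs), path)
    return refs


def load_repeats(path: str | Path) -> list[tuple[str, str]]:
    """Load a repeat-element FASTA as (id, DNA sequence) pairs."""
    out = []
    with _open_text(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            out.append((record.id, str(record.seq).upper().replace("U", "T")))
    return out


def write_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame as UTF-8 TSV with a header row and stable columns.

    Cells containing a tab are rejected outright instead of being quoted,
    so the files round-trip through :func:`read_table` byte-faithfully.
    """
    for col in records.columns:
        if records[col].dtype == object:
            values = records[col].dropna().astype(str)
            if values.str.contains("\t").any():
                raise ValueError(f"column {col!r} contains a tab character; refusing to write")
        if "\t" in str(col):
            raise ValueError(f"column name {col!r} contains a tab character")
    records.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t")


def load_manifest(path: str | Path) -> list[tuple[str, str]]:
    """Load a tissue manifest: two-column TSV ``sample_path<TAB>tissue``."""
    df = pd.read_csv(path, sep="\t")
    expected = ["sample_path", "tissue"]
    if list(df.columns) != expected:
        raise FormatError(
            f"{path}: manifest must have columns {expected}, found {list(df.columns)}"
        )
    return [(str(r.sample_path), str(r.tissue)) for r in df.itertuples()]


def write_fasta(reads: Iterator[SmallRNARead] | list[SmallRNARead], path: str | Path) -> None:
    """Write collapsed reads as FASTA with ``>seq<i>_x<count>`` headers."""
    with open(path, "w") as handle:
        for i, read in enumerate(reads):
            handle.write(f">seq{i}_x{read.count}\n{read.sequence}\n")


def write_fastq(records: list[tuple[str, str, str]], path: str | Path) -> None:
    """Write (id, sequence, quality-string) triples as Sanger FASTQ."""
    with open(path, "w") as handle:
        for name, seq, qual in records:
            handle.write(f"@{name}\n{seq}\n+\n{qual}\n")
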