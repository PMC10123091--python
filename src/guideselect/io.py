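"""File-format plumbing: FASTQ/FASTA via Biopython, YAML/JSON configs, TSV tables."""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .library import GuideLibrarySpec

__all__ = [
    "ReadRecord",
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "write_fasta",
    "load_spec",
    "save_spec",
    "save_json",
]


@dataclass
class ReadRecord:
    """A sequencing read: id, DNA sequence over {A,C,G,T,N}, optional quality."""

    id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        if any(b not in "ACGTN" for b in self.sequence):
            raise ValueError(f"read {self.id}: sequence must be over ACGTN")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(f"read {self.id}: quality length mismatch")


def _open_text(path: str | Path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream Phred+33 FASTQ records (gzip transparent)."""
    with _open_text(path, "r") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            qual = "".join(
                chr(q + 33) for q in rec.letter_annotations["phred_quality"]
            )
            yield ReadRecord(rec.id, str(rec.seq).upper(), qual)


def write_fastq(records: Iterable[ReadRecord], path: str | Path) -> int:
    """Write Phred+33 FASTQ (gzip if the path ends in .gz); returns count."""
    n = 0
    with _open_text(path, "w") as fh:
        for r in records:
            qual = r.quality or ("I" * len(r.sequence))  # Q40 placeholder
            seqrec = SeqRecord(Seq(r.sequence), id=r.id, description="")
            seqrec.letter_annotations["phred_quality"] = [
                ord(c) - 33 for c in qual
            ]
            SeqIO.write(seqrec, fh, "fastq")
            n += 1
    return n


def read_fasta(path: str | Path) -> dict[str, str]:
    with _open_text(path, "r") as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    with _open_text(path, "w") as fh:
        SeqIO.write(
            (SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()),
            fh,
            "fasta",
        )


def load_spec(path: str | Path) -> GuideLibrarySpec:
    """Read a GuideLibrarySpec from YAML or JSON."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return GuideLibrarySpec.from_dict(data)


def save_spec(spec: GuideLibrarySpec, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(spec.to_dict(), indent=2))
    else:
        path.write_text(yaml.safe_dump(spec.to_dict(), sort_keys=False))


def save_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


def _json_default(o):
    import numpy as np

    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
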