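"""Construct-library data model and file IO.

A screening library is a collection of lentiviral expression constructs,
each carrying one miRNA hairpin locus (the *insert*) cloned between fixed
vector-backbone sequences (the *flanks*).  The insert is what pooled-screen
sequencing reads are matched against; the flanks are shared by every
construct and serve as the universal-primer / anchor sequence.

Several constructs may carry variants or duplicates of the same miRNA
locus, so ``mirna_name`` is an annotation label that can repeat while
``construct_id`` is unique.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Construct",
    "ConstructLibrary",
    "PoolDesign",
    "LibraryError",
    "load_construct_library",
    "write_library",
    "make_pool_design",
    "load_pool_design",
    "write_pool_design",
]

_VALID_SEQ = re.compile(r"^[ACGT]*$")

TSV_COLUMNS = ["construct_id", "mirna_name", "candidate_flag", "titer", "insert_seq"]


class LibraryError(ValueError):
    """Raised for malformed or inconsistent library definitions."""


def _check_dna(seq: str, label: str, allow_empty: bool = False) -> str:
    seq = seq.upper()
    if not seq and not allow_empty:
        raise LibraryError(f"{label}: sequence is empty")
    m = _VALID_SEQ.match(seq)
    if m is None:
        for i, ch in enumerate(seq):
            if ch not in "ACGT":
                raise LibraryError(
                    f"{label}: non-ACGT character {ch!r} at position {i}"
                )
    return seq


@dataclass(frozen=True)
class Construct:
    """One expression construct: a miRNA locus insert plus vector flanks."""

    construct_id: str
    mirna_name: str
    insert_seq: str
    left_flank: str = ""
    right_flank: str = ""
    titer: float | None = None
    candidate_flag: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "insert_seq", _check_dna(self.insert_seq, self.construct_id)
        )
        object.__setattr__(
            self,
            "left_flank",
            _check_dna(self.left_flank, f"{self.construct_id} left_flank", True),
        )
        object.__setattr__(
            self,
            "right_flank",
            _check_dna(self.right_flank, f"{self.construct_id} right_flank", True),
        )
        if self.titer is not None and self.titer <= 0:
            raise LibraryError(f"{self.construct_id}: titer must be positive")


@dataclass
class ConstructLibrary:
    """Ordered, validated collection of constructs."""

    constructs: list[Construct]
    name: str = "library"

    def __post_init__(self) -> None:
        if len(self.constructs) == 0:
            raise LibraryError("library is empty")
        seen: set[str] = set()
        for c in self.constructs:
            if c.construct_id in seen:
                raise LibraryError(f"duplicate construct_id: {c.construct_id!r}")
            seen.add(c.construct_id)
        flanks = {(c.left_flank, c.right_flank) for c in self.constructs}
        if len(flanks) > 1:
            raise LibraryError(
                "left/right flanks differ between constructs; flanks are vector "
                "backbone and must be identical across the library"
            )

    def __len__(self) -> int:
        return len(self.constructs)

    def __iter__(self) -> Iterator[Construct]:
        return iter(self.constructs)

    def __getitem__(self, construct_id: str) -> Construct:
        for c in self.constructs:
            if c.construct_id == construct_id:
                return c
        raise KeyError(construct_id)

    @property
    def construct_ids(self) -> list[str]:
        return [c.construct_id for c in self.constructs]

    @property
    def left_flank(self) -> str:
        return self.constructs[0].left_flank

    @property
    def right_flank(self) -> str:
        return self.constructs[0].right_flank

    @property
    def n_distinct_names(self) -> int:
        return len({c.mirna_name for c in self.constructs})


@dataclass
class PoolDesign:
    """Partition of a library into pools of at most ``pool_size`` constructs."""

    pools: dict[str, list[str]]
    pool_size: int

    def __post_init__(self) -> None:
        if self.pool_size < 1:
            raise LibraryError("pool_size must be >= 1")
        seen: set[str] = set()
        for pid, members in self.pools.items():
            if len(members) > self.pool_size:
                raise LibraryError(
                    f"pool {pid!r} has {len(members)} members > pool_size {self.pool_size}"
                )
            for cid in members:
                if cid in seen:
                    raise LibraryError(f"construct {cid!r} assigned to multiple pools")
                seen.add(cid)

    @property
    def construct_ids(self) -> list[str]:
        return [cid for members in self.pools.values() for cid in members]

    def validate_against(self, library: ConstructLibrary) -> None:
        lib_ids = set(library.construct_ids)
        pool_ids = set(self.construct_ids)
        missing = lib_ids - pool_ids
        extra = pool_ids - lib_ids
        if missing or extra:
            raise LibraryError(
                f"pool design does not partition the library "
                f"(missing={sorted(missing)[:5]}, extra={sorted(extra)[:5]})"
            )


def _parse_bool(text: str) -> bool:
    return str(text).strip().lower() in {"1", "true", "yes", "y"}


def load_construct_library(
    path: str | Path,
    format: str = "tsv",
    *,
    left_flank: str = "",
    right_flank: str = "",
    name: str | None = None,
) -> ConstructLibrary:
    """Load a construct library from a FASTA or TSV file.

    FASTA headers follow ``>construct_id|mirna_name|candidate_flag``; flanks
    are vector sequence and must be supplied separately for FASTA input.
    TSV files carry the columns ``construct_id, mirna_name, candidate_flag,
    titer, insert_seq`` (header required; titer may be empty).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    name = name or path.stem
    constructs: list[Construct] = []
    if format == "fasta":
        for rec in SeqIO.parse(str(path), "fasta"):
            parts = rec.description.split("|")
            cid = parts[0].strip()
            mirna = parts[1].strip() if len(parts) > 1 else cid
            cand = _parse_bool(parts[2]) if len(parts) > 2 else False
            constructs.append(
                Construct(
                    construct_id=cid,
                    mirna_name=mirna,
                    insert_seq=str(rec.seq),
                    left_flank=left_flank,
                    right_flank=right_flank,
                    candidate_flag=cand,
                )
            )
    elif format == "tsv":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            if reader.fieldnames is None:
                raise LibraryError(f"{path}: empty file")
            missing = [c for c in TSV_COLUMNS if c not in reader.fieldnames]
            if missing:
                raise LibraryError(f"{path}: missing TSV columns {missing}")
            has_flanks = "left_flank" in reader.fieldnames
            for row in reader:
                lf = row["left_flank"] if has_flanks else left_flank
                rf = row["right_flank"] if has_flanks else right_flank
                titer_txt = (row.get("titer") or "").strip()
                constructs.append(
                    Construct(
                        construct_id=row["construct_id"].strip(),
                        mirna_name=row["mirna_name"].strip(),
                        insert_seq=row["insert_seq"].strip(),
                        left_flank=lf,
                        right_flank=rf,
                        titer=float(titer_txt) if titer_txt else None,
                        candidate_flag=_parse_bool(row["candidate_flag"]),
                    )
                )
    else:
        raise ValueError(f"unknown library format {format!r} (expected fasta or tsv)")
    if not constructs:
        raise LibraryError(f"{path}: no records found")
    return ConstructLibrary(constructs=constructs, name=name)


def write_library(library: ConstructLibrary, path: str | Path, format: str = "tsv") -> None:
    """Write a library to FASTA or TSV (the inverse of :func:`load_construct_library`)."""
    path = Path(path)
    if format == "fasta":
        records = [
            SeqRecord(
                Seq(c.insert_seq),
                id=f"{c.construct_id}|{c.mirna_name}|{str(c.candidate_flag).lower()}",
                description="",
            )
            for c in library
        ]
        SeqIO.write(records, str(path), "fasta")
    elif format == "tsv":
        cols = TSV_COLUMNS + ["left_flank", "right_flank"]
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(cols)
            for c in library:
                writer.writerow(
                    [
                        c.construct_id,
                        c.mirna_name,
                        str(c.candidate_flag).lower(),
                        "" if c.titer is None else repr(c.titer),
                        c.insert_seq,
                        c.left_flank,
                        c.right_flank,
                    ]
                )
    else:
        raise ValueError(f"unknown library format {format!r}")


def make_pool_design(
    library: ConstructLibrary, pool_size: int, seed: int
) -> PoolDesign:
    """Randomly partition the library into pools of at most ``pool_size``.

    Constructs are shuffled with the given seed and chunked; the last pool
    may be smaller.  Pool ids are ``pool01, pool02, ...``.
    """
    if pool_size < 1:
        raise LibraryError("pool_size must be >= 1")
    rng = np.random.default_rng(seed)
    ids = list(library.construct_ids)
    order = rng.permutation(len(ids))
    shuffled = [ids[i] for i in order]
    n_pools = math.ceil(len(ids) / pool_size)
    width = max(2, len(str(n_pools)))
    pools = {
        f"pool{(k + 1):0{width}d}": shuffled[k * pool_size : (k + 1) * pool_size]
        for k in range(n_pools)
    }
    return PoolDesign(pools=pools, pool_size=pool_size)


def write_pool_design(design: PoolDesign, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["pool_id", "construct_id"])
        for pid, members in design.pools.items():
            for cid in members:
                writer.writerow([pid, cid])


def load_pool_design(path: str | Path, pool_size: int | None = None) -> PoolDesign:
    pools: dict[str, list[str]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            pools.setdefault(row["pool_id"], []).append(row["construct_id"])
    if not pools:
        raise LibraryError(f"{path}: no pool assignments found")
    if pool_size is None:
        pool_size = max(len(m) for m in pools.values())
    return PoolDesign(pools=pools, pool_size=pool_size)
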