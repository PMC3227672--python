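"""Amplicon-read deconvolution: turn per-fraction FASTQ reads into
per-construct counts.

The amplicon structure is ``vector flank + insert (+ vector flank)``; every
read begins with (part of) the left vector flank because the sequencing
primer anneals there.  A read is processed in two steps:

1. *Anchor trimming* — locate the left-flank anchor inside the read by
   minimum Hamming distance over all offsets and cut it off.  Reads may be
   sequenced from either strand, so by default the reverse complement is
   tried when the forward orientation misses.
2. *Insert assignment* — compare the remaining fragment against the
   same-length prefix of every library insert and assign it to the unique
   nearest insert (Hamming), provided the distance is within tolerance.
   Ties are *ambiguous*; fragments too far from everything (or too short)
   are *unassigned*.

Nearest-neighbour prefix matching (rather than full alignment) is exact for
the substitution-only error model of short anchored amplicon reads and has
an obvious brute-force oracle, which the test-suite exploits.
"""

from __future__ import annotations

import gzip
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._seq import encode, revcomp, sliding_hamming
from .library import ConstructLibrary

__all__ = [
    "FRACTIONS",
    "UNASSIGNED",
    "AMBIGUOUS",
    "ReadCountTable",
    "InsertIndex",
    "locate_and_trim",
    "assign_insert",
    "count_reads",
]

FRACTIONS = ("control", "invasive")

UNASSIGNED = "unassigned"
AMBIGUOUS = "ambiguous"

DEFAULT_MAX_ANCHOR_MISMATCH = 2
DEFAULT_MAX_HAMMING = 5
DEFAULT_MIN_FRAGMENT = 20


@dataclass
class ReadCountTable:
    """Per-construct read counts for the control and invasive fractions.

    ``counts`` is indexed by construct_id with integer columns
    ``count_control`` and ``count_invasive``; constructs with zero reads are
    present with count 0.  Per fraction, assigned + unassigned + ambiguous
    equals total_reads (conservation).
    """

    counts: pd.DataFrame
    unassigned: dict[str, int] = field(default_factory=lambda: {f: 0 for f in FRACTIONS})
    ambiguous: dict[str, int] = field(default_factory=lambda: {f: 0 for f in FRACTIONS})
    total_reads: dict[str, int] | None = None

    def __post_init__(self) -> None:
        for f in FRACTIONS:
            col = f"count_{f}"
            if col not in self.counts.columns:
                raise ValueError(f"counts table lacks column {col!r}")
            if (self.counts[col] < 0).any():
                raise ValueError(f"negative counts in {col}")
        if self.total_reads is None:
            self.total_reads = {
                f: int(self.counts[f"count_{f}"].sum())
                + self.unassigned[f]
                + self.ambiguous[f]
                for f in FRACTIONS
            }
        self.validate()

    def validate(self) -> None:
        """Check the conservation invariant for both fractions."""
        for f in FRACTIONS:
            assigned = int(self.counts[f"count_{f}"].sum())
            total = assigned + self.unassigned[f] + self.ambiguous[f]
            if total != self.total_reads[f]:
                raise ValueError(
                    f"count conservation violated in fraction {f!r}: "
                    f"{assigned} assigned + {self.unassigned[f]} unassigned + "
                    f"{self.ambiguous[f]} ambiguous != {self.total_reads[f]} total"
                )

    def fraction_counts(self, fraction: str) -> pd.Series:
        return self.counts[f"count_{fraction}"]

    def summary(self) -> dict:
        return {
            "n_constructs": int(len(self.counts)),
            "total_reads": dict(self.total_reads),
            "unassigned": dict(self.unassigned),
            "ambiguous": dict(self.ambiguous),
        }

    def to_tsv(self, path: str | Path, sidecar: bool = True) -> None:
        df = self.counts.reset_index().rename(columns={"index": "construct_id"})
        df.to_csv(path, sep="\t", index=False, lineterminator="\n")
        if sidecar:
            Path(str(path) + ".summary.json").write_text(
                json.dumps(self.summary(), indent=2, sort_keys=True) + "\n"
            )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReadCountTable":
        df = pd.read_csv(path, sep="\t", dtype={"construct_id": str})
        df = df.set_index("construct_id")
        sidecar = Path(str(path) + ".summary.json")
        unassigned = {f: 0 for f in FRACTIONS}
        ambiguous = {f: 0 for f in FRACTIONS}
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            unassigned = {f: int(v) for f, v in meta.get("unassigned", unassigned).items()}
            ambiguous = {f: int(v) for f, v in meta.get("ambiguous", ambiguous).items()}
        return cls(counts=df, unassigned=unassigned, ambiguous=ambiguous)

    @classmethod
    def from_arrays(
        cls,
        construct_ids: list[str],
        control: np.ndarray,
        invasive: np.ndarray,
    ) -> "ReadCountTable":
        df = pd.DataFrame(
            {
                "count_control": np.asarray(control, dtype=np.int64),
                "count_invasive": np.asarray(invasive, dtype=np.int64),
            },
            index=pd.Index(construct_ids, name="construct_id"),
        )
        return cls(counts=df)


def locate_and_trim(
    read: str, anchor: str, max_anchor_mismatch: int = DEFAULT_MAX_ANCHOR_MISMATCH
) -> str | None:
    """Find the best occurrence of ``anchor`` in ``read`` and return the
    suffix following it, or None if no occurrence is within tolerance.

    The best occurrence minimises Hamming distance over all offsets; ties
    are broken by the leftmost offset.
    """
    if len(anchor) < 10:
        raise ValueError("anchor must be at least 10 nt")
    dists = sliding_hamming(encode(read), encode(anchor))
    if dists.size == 0:
        return None
    best = int(np.argmin(dists))  # argmin is leftmost on ties
    if int(dists[best]) > max_anchor_mismatch:
        return None
    return read[best + len(anchor) :]


class InsertIndex:
    """Pre-encoded insert prefixes for fast nearest-neighbour assignment."""

    def __init__(self, library: ConstructLibrary):
        self.construct_ids = list(library.construct_ids)
        self._inserts = [encode(c.insert_seq) for c in library]
        self._lens = np.array([len(a) for a in self._inserts])
        # pad to rectangular matrix for vectorised comparison
        maxlen = int(self._lens.max())
        mat = np.zeros((len(self._inserts), maxlen), dtype=np.uint8)
        for i, a in enumerate(self._inserts):
            mat[i, : len(a)] = a
        self._matrix = mat

    def nearest(self, fragment: str) -> tuple[int, int, int]:
        """Return (best_index, best_distance, n_tied) for a fragment against
        the same-length prefix of every insert (fragment truncated to the
        insert where the insert is shorter)."""
        frag = encode(fragment)
        L = len(frag)
        cmp_len = np.minimum(self._lens, L)
        m = self._matrix[:, :L]
        diff = m != frag[np.newaxis, : m.shape[1]]
        # positions beyond an insert's own length must not count as mismatches
        pos = np.arange(m.shape[1])
        valid = pos[np.newaxis, :] < cmp_len[:, np.newaxis]
        dists = np.count_nonzero(diff & valid, axis=1)
        best = int(np.argmin(dists))
        best_d = int(dists[best])
        n_tied = int(np.count_nonzero(dists == best_d))
        return best, best_d, n_tied


def assign_insert(
    fragment: str,
    library: ConstructLibrary | InsertIndex,
    max_hamming: int = DEFAULT_MAX_HAMMING,
    min_fragment: int = DEFAULT_MIN_FRAGMENT,
) -> str:
    """Assign a trimmed fragment to a construct by nearest prefix Hamming
    distance; returns the construct_id, ``"ambiguous"`` on a tie, or
    ``"unassigned"`` when nothing is close enough (or the fragment is
    shorter than ``min_fragment``)."""
    if not fragment:
        raise ValueError("fragment is empty")
    if len(fragment) < min_fragment:
        return UNASSIGNED
    index = library if isinstance(library, InsertIndex) else InsertIndex(library)
    best, best_d, n_tied = index.nearest(fragment)
    if best_d > max_hamming:
        return UNASSIGNED
    if n_tied >= 2:
        return AMBIGUOUS
    return index.construct_ids[best]


def _open_maybe_gzip(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _iter_reads(source) -> Iterator[str]:
    """Yield read sequences from a FASTQ path or an iterable of sequences /
    SeqRecords."""
    if isinstance(source, (str, Path)):
        with _open_maybe_gzip(Path(source)) as fh:
            it = SeqIO.parse(fh, "fastq")
            i = 0
            while True:
                try:
                    rec = next(it)
                except StopIteration:
                    break
                except ValueError as exc:
                    raise ValueError(f"unparseable FASTQ record #{i}: {exc}") from exc
                yield str(rec.seq)
                i += 1
    else:
        for rec in source:
            yield str(rec.seq) if hasattr(rec, "seq") else str(rec)


def _process_fraction(
    reads: Iterable[str],
    index: InsertIndex,
    anchor: str,
    right_flank: str,
    max_anchor_mismatch: int,
    max_hamming: int,
    min_fragment: int,
    rc_scan: bool,
) -> tuple[np.ndarray, int, int, int]:
    counts = np.zeros(len(index.construct_ids), dtype=np.int64)
    id_pos = {cid: i for i, cid in enumerate(index.construct_ids)}
    unassigned = ambiguous = total = 0
    for read in reads:
        total += 1
        fragment = locate_and_trim(read, anchor, max_anchor_mismatch)
        if fragment is None and rc_scan:
            fragment = locate_and_trim(revcomp(read), anchor, max_anchor_mismatch)
        if not fragment:
            unassigned += 1
            continue
        if right_flank and len(right_flank) >= 10:
            # trim read-through into the right vector flank, if any
            dists = sliding_hamming(encode(fragment), encode(right_flank))
            if dists.size:
                best = int(np.argmin(dists))
                if int(dists[best]) <= max_anchor_mismatch:
                    fragment = fragment[:best]
        if len(fragment) < min_fragment:
            unassigned += 1
            continue
        call = assign_insert(fragment, index, max_hamming, min_fragment)
        if call == UNASSIGNED:
            unassigned += 1
        elif call == AMBIGUOUS:
            ambiguous += 1
        else:
            counts[id_pos[call]] += 1
    return counts, unassigned, ambiguous, total


def count_reads(
    reads_control,
    reads_invasive,
    library: ConstructLibrary,
    max_anchor_mismatch: int = DEFAULT_MAX_ANCHOR_MISMATCH,
    max_hamming: int = DEFAULT_MAX_HAMMING,
    min_fragment: int = DEFAULT_MIN_FRAGMENT,
    anchor: str | None = None,
    rc_scan: bool = True,
) -> ReadCountTable:
    """Deconvolve the two screen fractions into a :class:`ReadCountTable`.

    ``reads_control`` / ``reads_invasive`` are FASTQ paths (plain or gzip)
    or iterables of reads.  The anchor defaults to the library's left vector
    flank.
    """
    if anchor is None:
        anchor = library.left_flank
    if len(anchor) < 10:
        raise ValueError("anchor (left flank) must be at least 10 nt")
    index = InsertIndex(library)
    results = {}
    for fraction, source in (("control", reads_control), ("invasive", reads_invasive)):
        counts, unassigned, ambiguous, total = _process_fraction(
            _iter_reads(source),
            index,
            anchor,
            library.right_flank,
            max_anchor_mismatch,
            max_hamming,
            min_fragment,
            rc_scan,
        )
        if total == 0:
            warnings.warn(f"fraction {fraction!r} contains no reads")
        results[fraction] = (counts, unassigned, ambiguous, total)
    df = pd.DataFrame(
        {
            "count_control": results["control"][0],
            "count_invasive": results["invasive"][0],
        },
        index=pd.Index(index.construct_ids, name="construct_id"),
    )
    return ReadCountTable(
        counts=df,
        unassigned={f: results[f][1] for f in FRACTIONS},
        ambiguous={f: results[f][2] for f in FRACTIONS},
        total_reads={f: results[f][3] for f in FRACTIONS},
    )
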