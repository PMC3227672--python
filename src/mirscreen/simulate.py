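"""Synthetic data generators for every input the screen pipeline consumes.

The pooled-screen generator embodies the generative process the analysis
assumes: clonally infected cells carrying one construct each are pooled
(40 constructs per pool), half of each pool is kept as the control
fraction, the other half passes through two rounds of invasion selection
with expansion back to the pool's population size in between, and both
fractions are read out by PCR amplification of the integrated constructs
(26 cycles with per-construct log-normal amplification bias) followed by
multinomial sequencing at a fixed per-fraction depth.

Ground truth (per-construct invasion probabilities and hit labels) is
returned with the simulated data so recovery can be scored exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import decode, encode, mutate, random_dna
from .deconvolution import ReadCountTable
from .library import Construct, ConstructLibrary, LibraryError, PoolDesign
from .plates import PlateGrid, well_to_rc
from .qpcr import QpcrTable

__all__ = [
    "ScreenTruth",
    "ScreenSimParams",
    "ScreenSimResult",
    "PlateSimParams",
    "generate_construct_library",
    "make_screen_truth",
    "simulate_pooled_screen",
    "simulate_plate",
    "simulate_qpcr",
    "write_fastq",
]


# ---------------------------------------------------------------------------
# construct library generation


def generate_construct_library(
    n_constructs: int,
    insert_len: int = 280,
    flank_len: int = 20,
    seed: int = 0,
    *,
    n_names: int | None = None,
    candidate_fraction: float = 422 / 1120,
    name: str = "synthetic-library",
) -> ConstructLibrary:
    """Generate a synthetic construct library with random inserts.

    Inserts are uniform-random ACGT sequences of ``insert_len`` nt,
    resampled until every pair differs by at least ``insert_len/4``
    positions, and share a single random flank pair of ``flank_len`` nt
    (the vector backbone / primer anchor).  ``n_names`` < ``n_constructs``
    makes some constructs share a miRNA name, modelling locus variants and
    duplicates.  Deterministic for a fixed seed.
    """
    if n_constructs < 1:
        raise ValueError("n_constructs must be >= 1")
    if insert_len < 20:
        raise ValueError("insert_len must be >= 20")
    if n_names is None:
        n_names = n_constructs
    if not 1 <= n_names <= n_constructs:
        raise ValueError("n_names must be in [1, n_constructs]")
    min_dist = insert_len // 4
    # crude capacity bound: random inserts of this length cannot keep large
    # libraries pairwise-distant, so fail early with actionable advice
    if n_constructs > 4 ** (insert_len / 8):
        raise LibraryError(
            f"insert_len {insert_len} is too short to guarantee {n_constructs} "
            f"inserts with pairwise Hamming distance >= {min_dist}; "
            "use a larger insert_len"
        )
    rng = np.random.default_rng(seed)
    left = random_dna(rng, flank_len)
    right = random_dna(rng, flank_len)
    accepted = np.empty((n_constructs, insert_len), dtype=np.uint8)
    n_acc = 0
    max_attempts = 200
    while n_acc < n_constructs:
        for _ in range(max_attempts):
            cand = encode(random_dna(rng, insert_len))
            if n_acc == 0:
                break
            dists = np.count_nonzero(accepted[:n_acc] != cand, axis=1)
            if int(dists.min()) >= min_dist:
                break
        else:
            raise LibraryError(
                f"could not draw {n_constructs} inserts of length {insert_len} "
                f"with pairwise distance >= {min_dist}; use a larger insert_len"
            )
        accepted[n_acc] = cand
        n_acc += 1
    width = max(3, len(str(n_constructs)))
    n_candidate = int(round(n_constructs * candidate_fraction))
    titers = rng.lognormal(mean=math.log(5.9e8), sigma=0.3, size=n_constructs)
    constructs = []
    for i in range(n_constructs):
        constructs.append(
            Construct(
                construct_id=f"c{i + 1:0{width}d}",
                mirna_name=f"mir-{(i % n_names) + 1:0{width}d}",
                insert_seq=decode(accepted[i]),
                left_flank=left,
                right_flank=right,
                titer=float(titers[i]),
                candidate_flag=(i >= n_constructs - n_candidate),
            )
        )
    return ConstructLibrary(constructs=constructs, name=name)


# ---------------------------------------------------------------------------
# pooled screen


@dataclass
class ScreenTruth:
    """Latent per-construct phenotype that the pooled screen estimates."""

    invasion_prob: dict[str, float]
    is_hit: dict[str, bool]
    background_prob: float

    def __post_init__(self) -> None:
        for cid, p in self.invasion_prob.items():
            if not 0 < p <= 1:
                raise ValueError(f"invasion_prob[{cid!r}] = {p} not in (0, 1]")
        for cid, p in self.invasion_prob.items():
            if self.is_hit[cid] != (p > self.background_prob):
                raise ValueError(
                    f"is_hit[{cid!r}] inconsistent with invasion_prob vs background"
                )

    @property
    def hit_ids(self) -> list[str]:
        return [cid for cid, h in self.is_hit.items() if h]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("construct_id\tinvasion_prob\tis_hit\n")
            for cid in self.invasion_prob:
                fh.write(
                    f"{cid}\t{self.invasion_prob[cid]!r}\t{str(self.is_hit[cid]).lower()}\n"
                )


def make_screen_truth(
    construct_ids: Sequence[str],
    hit_ids: Sequence[str],
    hit_prob: float = 0.5,
    background_prob: float = 0.05,
) -> ScreenTruth:
    """Two-level truth: hits invade with ``hit_prob`` per round, the rest
    with ``background_prob``."""
    hit_set = set(hit_ids)
    unknown = hit_set - set(construct_ids)
    if unknown:
        raise ValueError(f"hit ids not in library: {sorted(unknown)}")
    probs = {
        cid: (hit_prob if cid in hit_set else background_prob) for cid in construct_ids
    }
    return ScreenTruth(
        invasion_prob=probs,
        is_hit={cid: cid in hit_set for cid in construct_ids},
        background_prob=background_prob,
    )


@dataclass
class ScreenSimParams:
    """Parameters of the pooled-screen generative model.

    Defaults mirror the study conditions: ~5000 cells per construct
    (2x10^5 cells per 40-construct pool per invasion round), two rounds of
    selection, 26 total PCR cycles (20 primary + 3 secondary + 3 tertiary),
    and per-fraction sequencing depths of 0.9x10^6 (control) and 1.0x10^6
    (invasive) mapped reads.
    """

    cells_per_construct: int = 5000
    abundance_sigma: float = 0.25
    rounds: int = 2
    pcr_cycles: int = 26
    pcr_efficiency_sigma: float = 0.01
    depth_control: int = 900_000
    depth_invasive: int = 1_000_000
    read_error_rate: float = 0.005
    emit_reads: bool = False
    read_length: int = 50

    def __post_init__(self) -> None:
        if self.cells_per_construct < 1:
            raise ValueError("cells_per_construct must be >= 1")
        if self.abundance_sigma < 0 or self.pcr_efficiency_sigma < 0:
            raise ValueError("sigmas must be non-negative")
        if self.rounds < 0:
            raise ValueError("rounds must be >= 0")
        if self.pcr_cycles < 1:
            raise ValueError("pcr_cycles must be >= 1")
        if min(self.depth_control, self.depth_invasive) < 1:
            raise ValueError("depths must be positive")
        if not 0 <= self.read_error_rate < 1:
            raise ValueError("read_error_rate must be in [0, 1)")


@dataclass
class ScreenSimResult:
    counts: ReadCountTable
    truth: ScreenTruth
    reads_control: list[SeqRecord] | None = None
    reads_invasive: list[SeqRecord] | None = None
    seed: int | None = None


def _simulate_pool_population(
    rng: np.random.Generator,
    n_members: int,
    probs: np.ndarray,
    params: ScreenSimParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Return (control_cells, invasive_cells) for one pool."""
    n0 = np.round(
        rng.lognormal(
            mean=math.log(params.cells_per_construct),
            sigma=params.abundance_sigma,
            size=n_members,
        )
    ).astype(np.int64)
    total0 = int(n0.sum())
    inv = n0.copy()
    for _ in range(params.rounds):
        surv = rng.binomial(inv, probs)
        s = int(surv.sum())
        if s == 0:
            inv = np.zeros(n_members, dtype=np.int64)
            break
        # 2-3 week expansion back to the pool's population size, modelled
        # as multinomial regrowth proportional to survivors
        inv = rng.multinomial(total0, surv / s)
    return n0, inv


def simulate_pooled_screen(
    library: ConstructLibrary,
    design: PoolDesign,
    truth: ScreenTruth,
    params: ScreenSimParams | None = None,
    seed: int = 0,
) -> ScreenSimResult:
    """Simulate a pooled invasion screen with known ground truth.

    Per pool, initial clonal abundances are log-normal around
    ``cells_per_construct``; the control fraction reflects those
    abundances, the invasive fraction the survivors of ``rounds`` binomial
    selection rounds (with regrowth to constant pool size in between).
    Both fractions receive the same per-construct PCR amplification factor
    (bias cancels in enrichment but distorts abundance) and are sequenced
    as one multinomial draw per fraction at the requested depth, with
    pools contributing equal template mass (equal DNA input per pool).

    Child random streams are derived from the master seed by fixed
    arithmetic, so adding pools does not reshuffle existing ones.
    """
    params = params or ScreenSimParams()
    design.validate_against(library)
    missing = set(design.construct_ids) - set(truth.invasion_prob)
    if missing:
        raise ValueError(f"truth does not cover constructs: {sorted(missing)[:5]}")

    lib_ids = library.construct_ids
    pos = {cid: i for i, cid in enumerate(lib_ids)}
    n = len(lib_ids)

    # per-construct PCR amplification factor, shared by both fractions
    rng_pcr = np.random.default_rng([seed, 1])
    log_amp = rng_pcr.normal(math.log(2.0), params.pcr_efficiency_sigma, size=n)
    pcr_factor = np.exp(log_amp * params.pcr_cycles)

    control_w = np.zeros(n)
    invasive_w = np.zeros(n)
    for pool_index, pool_id in enumerate(sorted(design.pools)):
        members = design.pools[pool_id]
        idx = np.array([pos[cid] for cid in members])
        probs = np.array([truth.invasion_prob[cid] for cid in members])
        rng_pool = np.random.default_rng([seed, 100, pool_index])
        ctrl_cells, inv_cells = _simulate_pool_population(
            rng_pool, len(members), probs, params
        )
        if inv_cells.sum() == 0:
            warnings.warn(
                f"pool {pool_id!r}: no cells survived selection; it contributes "
                "no reads to the invasive fraction"
            )
        # equal DNA mass per pool: normalise each pool's template weights
        for cells, weights in ((ctrl_cells, control_w), (inv_cells, invasive_w)):
            w = cells * pcr_factor[idx]
            s = w.sum()
            if s > 0:
                weights[idx] += w / s

    counts = {}
    for fraction, weights, depth, stream in (
        ("control", control_w, params.depth_control, 2),
        ("invasive", invasive_w, params.depth_invasive, 3),
    ):
        rng_frac = np.random.default_rng([seed, stream])
        s = weights.sum()
        if s == 0:
            warnings.warn(f"fraction {fraction!r} has no template; zero reads")
            counts[fraction] = np.zeros(n, dtype=np.int64)
        else:
            counts[fraction] = rng_frac.multinomial(depth, weights / s)

    table = ReadCountTable.from_arrays(lib_ids, counts["control"], counts["invasive"])
    result = ScreenSimResult(counts=table, truth=truth, seed=seed)
    if params.emit_reads:
        result.reads_control = _emit_reads(
            library, counts["control"], params, np.random.default_rng([seed, 4])
        )
        result.reads_invasive = _emit_reads(
            library, counts["invasive"], params, np.random.default_rng([seed, 5])
        )
    return result


def _emit_reads(
    library: ConstructLibrary,
    counts: np.ndarray,
    params: ScreenSimParams,
    rng: np.random.Generator,
) -> list[SeqRecord]:
    """Materialise reads: left flank + insert prefix, fixed read length,
    i.i.d. substitution errors, shuffled order."""
    templates = []
    for c in library:
        amplicon = c.left_flank + c.insert_seq + c.right_flank
        templates.append(encode(amplicon[: params.read_length]))
    read_len = min(len(t) for t in templates)
    n_reads = int(counts.sum())
    if n_reads == 0:
        return []
    mat = np.empty((n_reads, read_len), dtype=np.uint8)
    origin = np.empty(n_reads, dtype=np.int64)
    row = 0
    for i, k in enumerate(counts):
        if k:
            mat[row : row + k] = templates[i][:read_len]
            origin[row : row + k] = i
            row += k
    mat = mutate(rng, mat, params.read_error_rate)
    order = rng.permutation(n_reads)
    ids = library.construct_ids
    records = []
    for j, r in enumerate(order):
        rec = SeqRecord(
            Seq(decode(mat[r])),
            id=f"read{j:07d}_{ids[origin[r]]}",
            description="",
        )
        rec.letter_annotations["phred_quality"] = [40] * read_len
        records.append(rec)
    return records


def write_fastq(records: list[SeqRecord], path: str | Path) -> None:
    SeqIO.write(records, str(path), "fastq")


# ---------------------------------------------------------------------------
# plates


@dataclass
class PlateSimParams:
    """Additive plate model: value = plate + row + column (+ hit) + noise."""

    n_rows: int = 8
    n_cols: int = 12
    plate_effect: float = 0.0
    row_effects: Sequence[float] | None = None
    col_effects: Sequence[float] | None = None
    noise_sd: float = 0.0
    hit_wells: Mapping[str, float] = field(default_factory=dict)
    control_wells: frozenset[str] | set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("plate must be at least 2x2")
        if self.row_effects is None:
            self.row_effects = [0.0] * self.n_rows
        if self.col_effects is None:
            self.col_effects = [0.0] * self.n_cols
        if len(self.row_effects) != self.n_rows:
            raise ValueError("row_effects length must equal n_rows")
        if len(self.col_effects) != self.n_cols:
            raise ValueError("col_effects length must equal n_cols")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for w in list(self.hit_wells) + list(self.control_wells):
            r, c = well_to_rc(w)
            if not (0 <= r < self.n_rows and 0 <= c < self.n_cols):
                raise ValueError(f"well {w!r} outside a {self.n_rows}x{self.n_cols} plate")
        overlap = set(self.hit_wells) & set(self.control_wells)
        if overlap:
            raise ValueError(f"control wells cannot carry hit effects: {sorted(overlap)}")


def simulate_plate(params: PlateSimParams, seed: int = 0) -> PlateGrid:
    """Simulate one plate readout under the additive model median polish
    assumes; control wells never receive hit effects."""
    rng = np.random.default_rng(seed)
    rows = np.asarray(params.row_effects, dtype=float)
    cols = np.asarray(params.col_effects, dtype=float)
    values = params.plate_effect + rows[:, None] + cols[None, :]
    values = values + rng.normal(0.0, params.noise_sd, size=values.shape)
    roles = np.full((params.n_rows, params.n_cols), "sample", dtype=object)
    for w, effect in params.hit_wells.items():
        r, c = well_to_rc(w)
        values[r, c] += effect
    for w in params.control_wells:
        r, c = well_to_rc(w)
        roles[r, c] = "control"
    return PlateGrid(values=values, roles=roles)


# ---------------------------------------------------------------------------
# qPCR


def simulate_qpcr(
    true_fold: Mapping[tuple[str, str], float],
    base_ct: float = 25.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    housekeeping: str = "U6",
    calibrator: str | None = None,
    n_replicates: int = 3,
) -> QpcrTable:
    """Invert the exponential-amplification model: one cycle per doubling,
    so Ct(sample, target) = base_ct - log2(fold) + noise.  The housekeeping
    target has fold 1 in every sample."""
    for key, fold in true_fold.items():
        if fold <= 0:
            raise ValueError(f"true_fold[{key}] must be positive")
    samples = sorted({s for s, _ in true_fold})
    if calibrator is None:
        calibrator = samples[0]
    rng = np.random.default_rng(seed)
    rows = []
    pairs = list(true_fold.items()) + [((s, housekeeping), 1.0) for s in samples]
    for (sample, target), fold in pairs:
        ct0 = base_ct - math.log2(fold)
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "sample_id": sample,
                    "target_id": target,
                    "replicate": rep,
                    "ct": ct0 + rng.normal(0.0, noise_sd),
                }
            )
    return QpcrTable(
        data=pd.DataFrame(rows), housekeeping=housekeeping, calibrator=calibrator
    )
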